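"""CorrTF spectral-ratio features.

The correlation transfer function between two regions is the per-frequency
ratio of their discrete Fourier transforms,

    CorrTF(i, j)[k] = DFT(x_i)[k] / DFT(x_j)[k],

read as the empirical transfer function of the communication path driving
region i from region j: if x_i were exactly x_j passed through an LTI
system with impulse response h (circularly over the T retained samples),
the ratio would equal H(f) = DFT(h) at every bin. Per subject this yields
a complex R x R x T tensor; Fisher's r-to-z transform (arctanh) of the
ratio magnitudes followed by averaging over the frequency bins produces
the real R x R connectivity feature matrix, flattened over off-diagonal
cells into the classifier's feature vector.

Two numerical guards keep the features finite:

* bins where the denominator spectrum is negligible (relative magnitude
  below ``eps_den``) yield ratio 0 and are flagged instead of dividing;
* ratio magnitudes are clipped to 1 - ``eps_clip`` before arctanh, since
  gains above 1 fall outside the transform's domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .timeseries import ROITimeSeries

logger = logging.getLogger(__name__)

EPS_DEN = 1e-8
EPS_CLIP = 1e-6


@dataclass
class CorrTFTensor:
    """Complex R x R x F spectral-ratio tensor for one subject."""

    values: np.ndarray          # complex (R, R, F)
    freq_hz: np.ndarray         # (F,)
    roi_ids: list
    guarded: np.ndarray = None  # bool (R, R, F); True where the guard fired

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_freqs(self) -> int:
        return self.values.shape[2]


@dataclass
class ConnectivityFeatureMatrix:
    """Real R x R matrix of frequency-averaged Fisher-z CorrTF values."""

    values: np.ndarray
    roi_ids: list
    diagonal_excluded: bool = True


@dataclass
class FeatureVector:
    """Flattened off-diagonal features, row-major over (i, j), i != j."""

    values: np.ndarray
    edge_index: list  # of (roi_id_i, roi_id_j)

    def __post_init__(self):
        if len(self.values) != len(self.edge_index):
            raise ValueError("values and edge_index lengths differ")


def _denominator_guard_mask(Y: np.ndarray, eps_den: float) -> np.ndarray:
    """Bins where |DFT(y)| is negligible relative to its own maximum."""
    mag = np.abs(Y)
    return mag < eps_den * mag.max(axis=-1, keepdims=True)


def corrtf_pair(x, y, eps_den: float = EPS_DEN, guard: bool = True):
    """Per-bin DFT ratio of two equal-length series.

    Returns (spectrum, guarded_mask); ``spectrum[k] = DFT(x)[k]/DFT(y)[k]``
    except at guarded bins, which are set to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series shapes differ or are not 1-D: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("series must have length >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    X = np.fft.fft(x)
    Y = np.fft.fft(y)
    if not guard:
        if not np.any(y):
            raise ValueError("all-zero denominator series with guard disabled")
        with np.errstate(divide="ignore", invalid="ignore"):
            return X / Y, np.zeros(x.size, dtype=bool)
    mask = _denominator_guard_mask(Y, eps_den)
    ratio = np.zeros(x.size, dtype=complex)
    np.divide(X, Y, out=ratio, where=~mask)
    return ratio, mask


def corrtf_tensor(ts: ROITimeSeries, eps_den: float = EPS_DEN) -> CorrTFTensor:
    """All-pairs spectral-ratio tensor, shape R x R x T.

    ``values[i, j, :]`` is the CorrTF spectrum with ROI row i as numerator
    (output) and row j as denominator (input), so a planted kernel driving
    target t from source s appears at cell (t, s).
    """
    F = np.fft.fft(ts.values, axis=1)               # (R, T)
    dmask = _denominator_guard_mask(F, eps_den)     # (R, T) per-denominator
    R, T = F.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = F[:, None, :] / F[None, :, :]       # (R, R, T)
    guarded = np.broadcast_to(dmask[None, :, :], ratio.shape).copy()
    ratio[guarded] = 0.0
    freq = np.fft.fftfreq(T, d=ts.tr_seconds)
    return CorrTFTensor(ratio, freq_hz=freq, roi_ids=list(ts.roi_ids), guarded=guarded)


def fisher_z(
    tensor,
    eps_clip: float = EPS_CLIP,
    mode: str = "magnitude",
    return_clip_count: bool = False,
):
    """Fisher r-to-z (arctanh) of the ratio tensor, real-valued and finite.

    mode='magnitude' (default) transforms the gain |ratio|; mode='real'
    transforms the real part, clipped symmetrically to (-1, 1).
    """
    values = tensor.values if isinstance(tensor, CorrTFTensor) else np.asarray(tensor)
    if mode == "magnitude":
        raw = np.abs(values)
        clipped = np.clip(raw, 0.0, 1.0 - eps_clip)
    elif mode == "real":
        raw = np.real(values)
        clipped = np.clip(raw, -1.0 + eps_clip, 1.0 - eps_clip)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n_clipped = int(np.count_nonzero(clipped != raw))
    if n_clipped:
        logger.debug("fisher_z clipped %d entries to the arctanh domain", n_clipped)
    z = np.arctanh(clipped)
    if return_clip_count:
        return z, n_clipped
    return z


def average_over_freq(
    z_tensor: np.ndarray,
    roi_ids=None,
    freq_hz=None,
    band=None,
) -> ConnectivityFeatureMatrix:
    """Mean over the frequency axis; diagonal zeroed and flagged excluded.

    By default all F bins are averaged. Passing ``band=(low, high)`` with
    ``freq_hz`` restricts the mean to bins with low <= |f| <= high.
    """
    z = np.asarray(z_tensor, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z tensor contains non-finite entries")
    if band is not None:
        if freq_hz is None:
            raise ValueError("band averaging requires freq_hz")
        low, high = band
        keep = (np.abs(freq_hz) >= low) & (np.abs(freq_hz) <= high)
        if not keep.any():
            raise ValueError("no frequency bins inside the requested band")
        mat = z[:, :, keep].mean(axis=2)
    else:
        mat = z.mean(axis=2)
    np.fill_diagonal(mat, 0.0)
    if roi_ids is None:
        roi_ids = list(range(1, mat.shape[0] + 1))
    return ConnectivityFeatureMatrix(mat, roi_ids=list(roi_ids), diagonal_excluded=True)


def offdiag_edge_index(roi_ids) -> list:
    """Row-major ordering of off-diagonal (roi_i, roi_j) cells."""
    return [(a, b) for a in roi_ids for b in roi_ids if a != b]


def flatten_features(matrix: ConnectivityFeatureMatrix) -> FeatureVector:
    R = matrix.values.shape[0]
    mask = ~np.eye(R, dtype=bool)
    return FeatureVector(
        values=matrix.values[mask].copy(),
        edge_index=offdiag_edge_index(matrix.roi_ids),
    )


def subject_features(
    ts: ROITimeSeries,
    mode: str = "magnitude",
    band_limited: bool = False,
    eps_den: float = EPS_DEN,
    eps_clip: float = EPS_CLIP,
    passband=(0.01, 0.08),
) -> FeatureVector:
    """Full per-subject pipeline: ratio tensor -> Fisher z -> mean -> flatten."""
    tensor = corrtf_tensor(ts, eps_den=eps_den)
    z = fisher_z(tensor, eps_clip=eps_clip, mode=mode)
    matrix = average_over_freq(
        z,
        roi_ids=tensor.roi_ids,
        freq_hz=tensor.freq_hz,
        band=passband if band_limited else None,
    )
    return flatten_features(matrix)


def subject_feature_matrix(ts: ROITimeSeries, **kwargs) -> ConnectivityFeatureMatrix:
    """R x R feature matrix for one subject (un-flattened form)."""
    tensor = corrtf_tensor(ts, eps_den=kwargs.pop("eps_den", EPS_DEN))
    z = fisher_z(
        tensor,
        eps_clip=kwargs.pop("eps_clip", EPS_CLIP),
        mode=kwargs.pop("mode", "magnitude"),
    )
    band_limited = kwargs.pop("band_limited", False)
    passband = kwargs.pop("passband", (0.01, 0.08))
    if kwargs:
        raise TypeError(f"unexpected arguments {sorted(kwargs)}")
    return average_over_freq(
        z,
        roi_ids=tensor.roi_ids,
        freq_hz=tensor.freq_hz,
        band=passband if band_limited else None,
    )


class CorrTFTransformer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: ROI time series -> CorrTF feature rows.

    Accepts a list of :class:`~corrtf.timeseries.ROITimeSeries` or an
    (n_subjects, R, T) array and returns (n_subjects, R*(R-1)) features.

    Parameters
    ----------
    mode : {'magnitude', 'real'}
        How complex spectral ratios are made real before arctanh.
    band_limited : bool
        Average only bins inside ``passband`` instead of all T bins.
    tr_seconds : float
        Sampling interval assumed when raw arrays (not ROITimeSeries)
        are passed.
    """

    def __init__(
        self,
        mode: str = "magnitude",
        band_limited: bool = False,
        passband=(0.01, 0.08),
        eps_den: float = EPS_DEN,
        eps_clip: float = EPS_CLIP,
        tr_seconds: float = 3.0,
    ):
        self.mode = mode
        self.band_limited = band_limited
        self.passband = passband
        self.eps_den = eps_den
        self.eps_clip = eps_clip
        self.tr_seconds = tr_seconds

    def fit(self, X, y=None):
        first = self._as_ts(X[0])
        self.n_rois_ = first.n_rois
        self.edge_index_ = offdiag_edge_index(first.roi_ids)
        return self

    def _as_ts(self, item) -> ROITimeSeries:
        if isinstance(item, ROITimeSeries):
            return item
        return ROITimeSeries(np.asarray(item, dtype=float), tr_seconds=self.tr_seconds)

    def transform(self, X) -> np.ndarray:
        rows = []
        for item in X:
            fv = subject_features(
                self._as_ts(item),
                mode=self.mode,
                band_limited=self.band_limited,
                eps_den=self.eps_den,
                eps_clip=self.eps_clip,
                passband=self.passband,
            )
            rows.append(fv.values)
        return np.vstack(rows)


def cohort_features(subject_ts_list, **kwargs):
    """Feature matrix (n_subjects, R*(R-1)) plus the shared edge index."""
    tf = CorrTFTransformer(**kwargs)
    ts0 = tf._as_ts(subject_ts_list[0])
    X = tf.fit(subject_ts_list).transform(subject_ts_list)
    return X, offdiag_edge_index(ts0.roi_ids), list(ts0.roi_ids)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_feature_matrix_tsv(matrix: ConnectivityFeatureMatrix, path) -> None:
    pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.roi_ids, name="roi_id"),
        columns=matrix.roi_ids,
    ).to_csv(path, sep="\t")


def read_feature_matrix_tsv(path) -> ConnectivityFeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityFeatureMatrix(
        df.to_numpy(dtype=float), roi_ids=[int(v) for v in df.index]
    )


def write_cohort_features_tsv(X, edge_index, subject_ids, path) -> None:
    cols = [f"{a}->{b}" for a, b in edge_index]
    pd.DataFrame(X, index=pd.Index(subject_ids, name="subject_id"), columns=cols).to_csv(
        path, sep="\t"
    )


def read_cohort_features_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    edge_index = []
    for col in df.columns:
        a, b = col.split("->")
        edge_index.append((int(a), int(b)))
    return df.to_numpy(dtype=float), edge_index, [str(s) for s in df.index]
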
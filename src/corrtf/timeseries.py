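"""ROI mean time-series extraction and band-pass filtering for rs-fMRI.

A subject enters the pipeline as a preprocessed 4D BOLD volume plus an
integer-labeled atlas image (e.g. the 116-region AAL parcellation), or
directly as an R x T matrix of ROI mean signals. This module produces the
band-passed :class:`ROITimeSeries` the CorrTF feature extractor consumes.

Motion correction, slice timing, spatial normalisation and smoothing are
assumed to have been done upstream; they are not reimplemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class ROITimeSeries:
    """One subject's R x T matrix of ROI mean BOLD signals.

    Parameters
    ----------
    values : ndarray, shape (R, T)
        Mean signal of each region at each retained time point (a.u.).
    roi_ids : list of int
        Atlas labels, one per row, in ascending atlas-label order.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    """

    values: np.ndarray
    roi_ids: list = field(default_factory=list)
    tr_seconds: float = 3.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (R x T) array")
        if not self.roi_ids:
            self.roi_ids = list(range(1, self.values.shape[0] + 1))
        if len(self.roi_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.roi_ids)} roi_ids for {self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in ROI time series")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def fs_hz(self) -> float:
        """Sampling frequency in Hz."""
        return 1.0 / self.tr_seconds


def _as_array(volume) -> np.ndarray:
    """Accept a nibabel spatial image or a plain ndarray."""
    if hasattr(volume, "get_fdata"):
        return np.asarray(volume.get_fdata())
    return np.asarray(volume, dtype=float)


def extract_mean_timeseries(
    volume4d,
    atlas_labels,
    discard_initial: int = 10,
    roi_ids=None,
    tr_seconds: float = 3.0,
) -> ROITimeSeries:
    """Average voxels within each atlas label at every retained time point.

    The first ``discard_initial`` volumes are dropped (magnetisation
    equilibration), so an acquisition of 140 volumes yields T = 130.

    Parameters
    ----------
    volume4d : ndarray or nibabel image, shape (X, Y, Z, T_total)
    atlas_labels : ndarray or nibabel image, shape (X, Y, Z)
        Integer labels; 0 is background and never averaged.
    discard_initial : int
        Number of leading volumes to discard.
    roi_ids : sequence of int, optional
        Labels to extract. Default: all distinct nonzero labels, ascending.
    tr_seconds : float
        Repetition time of the acquisition.
    """
    data = _as_array(volume4d)
    atlas = _as_array(atlas_labels)
    atlas = np.asarray(np.rint(atlas), dtype=int)
    if data.ndim != 4:
        raise ValueError("volume4d must be 4-dimensional")
    if atlas.shape != data.shape[:3]:
        raise ValueError(
            f"atlas shape {atlas.shape} does not match volume spatial shape "
            f"{data.shape[:3]}"
        )
    if data.shape[3] < discard_initial + 2:
        raise ValueError(
            f"need at least {discard_initial + 2} volumes, got {data.shape[3]}"
        )
    if roi_ids is None:
        roi_ids = sorted(int(v) for v in np.unique(atlas) if v != 0)
    else:
        roi_ids = sorted(int(v) for v in roi_ids)

    data = data[..., discard_initial:]
    flat = data.reshape(-1, data.shape[3])
    labels_flat = atlas.reshape(-1)
    rows = []
    for label in roi_ids:
        mask = labels_flat == label
        if not mask.any():
            raise ValueError(f"atlas label {label} not present in atlas image")
        rows.append(flat[mask].mean(axis=0))
    return ROITimeSeries(np.vstack(rows), roi_ids=list(roi_ids), tr_seconds=tr_seconds)


def bandpass(
    ts: ROITimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 5,
) -> ROITimeSeries:
    """Zero-phase Butterworth band-pass of every ROI row.

    Forward-backward (``sosfiltfilt``) application keeps the filter
    zero-phase, which matters here because CorrTF measures inter-ROI
    phase relationships: a causal filter would add a spurious common
    phase ramp to every region.
    """
    nyq = 0.5 * ts.fs_hz
    if not (0.0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyq:.4g} Hz"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=ts.fs_hz, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, ts.values, axis=1)
    return replace(ts, values=np.ascontiguousarray(filtered))


# ---------------------------------------------------------------------------
# TSV I/O: rows = ROIs, columns = time points, first column = ROI label.
# ---------------------------------------------------------------------------

def write_timeseries_tsv(ts: ROITimeSeries, path) -> None:
    df = pd.DataFrame(
        ts.values,
        index=pd.Index(ts.roi_ids, name="roi_id"),
        columns=[f"t{k}" for k in range(ts.n_timepoints)],
    )
    df.to_csv(path, sep="\t")


def read_timeseries_tsv(path, tr_seconds: float = 3.0) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ROITimeSeries(
        df.to_numpy(dtype=float),
        roi_ids=[int(v) for v in df.index],
        tr_seconds=tr_seconds,
    )


def write_labels_tsv(labels: dict, path) -> None:
    """Write subject_id -> diagnostic label pairs."""
    pd.DataFrame(
        {"subject_id": list(labels), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["subject_id"].astype(str), df["label"].astype(str)))
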
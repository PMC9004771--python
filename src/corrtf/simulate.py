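"""Synthetic rs-fMRI cohorts with planted inter-ROI transfer functions.

The generator emulates the signal model the CorrTF feature targets: every
region carries a band-limited (0.01-0.08 Hz at TR = 3 s) BOLD-like signal,
and selected region pairs are coupled by a known linear time-invariant
kernel, i.e. the target region's series is the circular convolution of the
source region's series with a finite impulse response h, plus Gaussian
observation noise. Because the convolution is circular over the T retained
points, the DFT ratio of target to source equals H(f) = DFT(h) exactly,
which gives the CorrTF estimator a clean recovery oracle.

Diagnostic groups differ only through the kernels planted on a shared edge
set, mirroring the idea that disease progression alters the inter-regional
communication path rather than the regional signals themselves.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np

from .timeseries import ROITimeSeries

VALID_LABELS = ("NC", "EMCI", "LMCI", "AD")

#: Amplitude of the out-of-band spectral floor relative to the passband.
#: A -60 dB floor keeps out-of-band power ~1e-6 of in-band per bin (far
#: below the 1% band-limitation budget) while leaving every DFT bin of a
#: base signal nonzero, so spectral ratios stay well defined at all bins.
OUT_OF_BAND_FLOOR = 1e-3


@dataclass(frozen=True)
class KernelSpec:
    """A planted linear coupling: target = source (*) impulse_response + noise.

    ROI indices are 1-based atlas-style labels.
    """

    source_roi: int
    target_roi: int
    impulse_response: tuple
    noise_sd: float = 0.0

    def __post_init__(self):
        object.__setattr__(
            self, "impulse_response", tuple(float(v) for v in self.impulse_response)
        )
        if self.source_roi == self.target_roi:
            raise ValueError("kernel source and target ROI must differ")
        if len(self.impulse_response) < 1:
            raise ValueError("impulse_response needs at least one tap")
        if not np.all(np.isfinite(self.impulse_response)):
            raise ValueError("impulse_response taps must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int
    kernels: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "kernels", tuple(self.kernels))
        if self.label not in VALID_LABELS:
            raise ValueError(f"label {self.label!r} not in {VALID_LABELS}")
        if self.n_subjects < 1:
            raise ValueError("each group needs at least one subject")


@dataclass(frozen=True)
class SimConfig:
    """Cohort generation parameters.

    Defaults mirror the acquisition the pipeline is designed around:
    116 regions, 130 retained time points at TR = 3 s (140 acquired minus
    10 discarded), passband 0.01-0.08 Hz.
    """

    groups: tuple
    n_rois: int = 116
    n_timepoints: int = 130
    tr_seconds: float = 3.0
    passband: tuple = (0.01, 0.08)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "passband", tuple(self.passband))
        if self.n_timepoints < 16:
            raise ValueError("n_timepoints must be >= 16")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        low, high = self.passband
        nyq = 1.0 / (2.0 * self.tr_seconds)
        if not (0.0 < low < high < nyq):
            raise ValueError(
                f"passband {self.passband} must satisfy 0 < low < high < {nyq:.4g}"
            )
        for g in self.groups:
            _validate_kernels(g.kernels, self.n_rois)


def _validate_kernels(kernels, n_rois: int) -> None:
    """ROI indices in range, one kernel per target, and the edge set is a DAG."""
    targets = set()
    edges = []
    for ks in kernels:
        for roi in (ks.source_roi, ks.target_roi):
            if not 1 <= roi <= n_rois:
                raise ValueError(f"kernel ROI index {roi} outside 1..{n_rois}")
        if ks.target_roi in targets:
            raise ValueError(
                f"ROI {ks.target_roi} is the target of more than one kernel"
            )
        targets.add(ks.target_roi)
        edges.append((ks.source_roi, ks.target_roi))
    sorter = graphlib.TopologicalSorter()
    for src, tgt in edges:
        sorter.add(tgt, src)  # target depends on source
    try:
        sorter.prepare()
    except graphlib.CycleError as exc:
        raise ValueError(f"kernel edges form a cycle: {exc.args[1]}") from exc


@dataclass
class SyntheticCohort:
    """Generated subjects plus the ground-truth discriminative edge set."""

    subjects: list  # of (subject_id, label, ROITimeSeries)
    ground_truth_edges: set = field(default_factory=set)
    config: SimConfig = None

    @property
    def labels(self) -> dict:
        return {sid: lab for sid, lab, _ in self.subjects}


def _passband_mask(n_timepoints: int, tr_seconds: float, passband) -> np.ndarray:
    """Boolean in-band mask over the rfft bins."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    low, high = passband
    return (freqs >= low) & (freqs <= high)


def _base_signals(rng, n_rois, n_timepoints, tr_seconds, passband) -> np.ndarray:
    """Band-limited zero-mean unit-variance Gaussian rows.

    White noise is shaped in the DFT domain: unit gain in the passband and
    a small floor (OUT_OF_BAND_FLOOR) outside, then z-scored per row.
    """
    white = rng.standard_normal((n_rois, n_timepoints))
    spec = np.fft.rfft(white, axis=1)
    mask = _passband_mask(n_timepoints, tr_seconds, passband)
    gain = np.where(mask, 1.0, OUT_OF_BAND_FLOOR)
    shaped = np.fft.irfft(spec * gain, n=n_timepoints, axis=1)
    shaped -= shaped.mean(axis=1, keepdims=True)
    shaped /= shaped.std(axis=1, keepdims=True)
    return shaped


def circular_convolve(x: np.ndarray, h) -> np.ndarray:
    """Circular convolution of a length-T series with a zero-padded kernel."""
    x = np.asarray(x, dtype=float)
    hpad = np.zeros_like(x)
    taps = np.asarray(h, dtype=float)
    if taps.size > x.size:
        raise ValueError("kernel longer than the time series")
    hpad[: taps.size] = taps
    return np.real(np.fft.ifft(np.fft.fft(x) * np.fft.fft(hpad)))


def _topological_kernel_order(kernels):
    by_target = {ks.target_roi: ks for ks in kernels}
    sorter = graphlib.TopologicalSorter()
    for ks in kernels:
        sorter.add(ks.target_roi, ks.source_roi)
    return [by_target[roi] for roi in sorter.static_order() if roi in by_target]


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a labeled multi-group cohort; bit-identical given the seed."""
    rng = np.random.default_rng(config.seed)
    subjects = []
    for group in config.groups:
        ordered = _topological_kernel_order(group.kernels)
        for i in range(group.n_subjects):
            base = _base_signals(
                rng, config.n_rois, config.n_timepoints,
                config.tr_seconds, config.passband,
            )
            for ks in ordered:
                src = base[ks.source_roi - 1]
                noise = rng.normal(0.0, ks.noise_sd, size=config.n_timepoints)
                base[ks.target_roi - 1] = (
                    circular_convolve(src, ks.impulse_response) + noise
                )
            ts = ROITimeSeries(
                base,
                roi_ids=list(range(1, config.n_rois + 1)),
                tr_seconds=config.tr_seconds,
            )
            subjects.append((f"sub-{group.label}{i:03d}", group.label, ts))
    return SyntheticCohort(
        subjects=subjects,
        ground_truth_edges=_differing_edges(config.groups),
        config=config,
    )


def _differing_edges(groups) -> set:
    """Edges whose kernel differs across groups (including edges absent in some)."""
    edge_kernels: dict = {}
    for group in groups:
        for ks in group.kernels:
            edge_kernels.setdefault((ks.source_roi, ks.target_roi), {})[
                group.label
            ] = ks.impulse_response
    labels = [g.label for g in groups]
    out = set()
    for edge, per_group in edge_kernels.items():
        seen = {per_group.get(lab) for lab in labels}
        if len(seen) > 1:
            out.add(edge)
    return out


# ---------------------------------------------------------------------------
# Tiny labeled 4D volumes for end-to-end I/O testing
# ---------------------------------------------------------------------------

def block_layout(roi_ids, voxels_per_roi: int = 8):
    """Disjoint cubic-ish voxel blocks along the x axis, one per ROI.

    Returns (shape, {roi_id: (n_voxels, 3) int coordinate array}).
    """
    side = max(1, int(np.ceil(voxels_per_roi ** (1 / 3))))
    coords = {}
    x0 = 0
    for roi in roi_ids:
        block = []
        for n in range(voxels_per_roi):
            i, rem = divmod(n, side * side)
            j, k = divmod(rem, side)
            block.append((x0 + i, j, k))
        coords[roi] = np.array(block, dtype=int)
        x0 += side + 1  # gap of background between blocks
    shape = (x0, side, side)
    return shape, coords


def generate_labeled_volume(
    ts: ROITimeSeries,
    layout=None,
    voxels_per_roi: int = 1,
    voxel_noise_sd: float = 0.0,
    rng=None,
):
    """Paint each ROI's series into a voxel block of a synthetic 4D volume.

    With ``voxel_noise_sd = 0`` the per-label voxel mean at every time point
    reproduces the input series exactly; with noise, to within the standard
    error of the mean.

    Returns a pair of nibabel images (4D data, 3D integer labels).
    """
    import nibabel as nib

    if layout is None:
        layout = block_layout(ts.roi_ids, voxels_per_roi)
    shape, coords = layout
    labels = np.zeros(shape, dtype=np.int16)
    for roi, vox in coords.items():
        if roi not in ts.roi_ids:
            raise ValueError(f"layout ROI {roi} not present in the time series")
        if np.any(labels[vox[:, 0], vox[:, 1], vox[:, 2]] != 0):
            raise ValueError(f"voxel block for ROI {roi} overlaps another block")
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = roi
    for roi in ts.roi_ids:
        if roi not in coords or len(coords[roi]) == 0:
            raise ValueError(f"ROI {roi} has no voxels in the layout")

    data = np.zeros(shape + (ts.n_timepoints,), dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    for row, roi in enumerate(ts.roi_ids):
        vox = coords[roi]
        series = ts.values[row]
        for x, y, z in vox:
            noise = (
                rng.normal(0.0, voxel_noise_sd, size=ts.n_timepoints)
                if voxel_noise_sd > 0
                else 0.0
            )
            data[x, y, z, :] = series + noise

    affine = np.eye(4)
    return nib.Nifti1Image(data, affine), nib.Nifti1Image(labels, affine)


# ---------------------------------------------------------------------------
# Default four-group study configuration
# ---------------------------------------------------------------------------

def default_cohort_config(
    n_per_class: int = 40,
    n_rois: int = 16,
    n_timepoints: int = 130,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SimConfig:
    """Four-stage cohort with hierarchy-aligned planted effects.

    Six directed edges carry group-specific scalar gains, all below 1
    (the Fisher-z clip at magnitude 1 makes larger gains indistinguishable):

    * edges 1->2, 3->4 separate AD from everyone (largest gap),
    * edges 5->6, 7->8 separate NC from the two MCI stages,
    * edges 9->10, 11->12 separate EMCI from LMCI (smallest gap).

    The gaps shrink down the hierarchy, emulating a staging problem where
    the most advanced disease is easiest to recognise.
    """
    if n_rois < 12:
        raise ValueError("default config plants edges on ROIs 1..12; need n_rois >= 12")

    gains = {
        #        1->2   3->4   5->6   7->8   9->10  11->12
        "NC":   (0.80,  0.80,  0.90,  0.90,  0.675, 0.675),
        "EMCI": (0.80,  0.80,  0.65,  0.65,  0.80,  0.80),
        "LMCI": (0.80,  0.80,  0.65,  0.65,  0.55,  0.55),
        "AD":   (0.25,  0.25,  0.65,  0.65,  0.675, 0.675),
    }
    edges = [(1, 2), (3, 4), (5, 6), (7, 8), (9, 10), (11, 12)]
    groups = []
    for label in VALID_LABELS:
        kernels = tuple(
            KernelSpec(src, tgt, (g,), noise_sd=noise_sd)
            for (src, tgt), g in zip(edges, gains[label])
        )
        groups.append(GroupSpec(label, n_per_class, kernels))
    return SimConfig(
        groups=tuple(groups),
        n_rois=n_rois,
        n_timepoints=n_timepoints,
        seed=seed,
    )
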
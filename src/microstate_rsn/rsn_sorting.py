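"""Temporal sorting of fMRI resting-state-network time courses.

Each subject's microstate segmentation is turned into per-state boxcar
timings, convolved with the canonical double-gamma HRF on a fine time
grid, and sampled at the scanner TR.  Component time courses are then
regressed jointly on the K microstate regressors; group-averaged slopes
are standardized across components within each microstate x group cell,
and pairings with Z >= 1 are flagged for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .backfit import Segmentation

#: canonical double-gamma HRF parameters (seconds / ratio)
DEFAULT_HRF = {
    "peak_delay": 6.0,
    "undershoot_delay": 16.0,
    "peak_disp": 1.0,
    "undershoot_disp": 1.0,
    "undershoot_ratio": 6.0,
    "length": 32.0,
}

#: fine-grid rate (Hz) for boxcar construction before HRF convolution;
#: microstate runs (~100 ms) are far below the TR, so binning at the TR
#: first would alias them away
FINE_HZ = 100.0


@dataclass
class RSNTimecourseSet:
    """Per-subject component x volume matrix of RSN time courses."""

    timecourses: np.ndarray
    tr_s: float = 2.2
    component_names: tuple[str, ...] = ()
    subject_id: str = "s00"
    group: str = "control"

    def __post_init__(self):
        tc = np.asarray(self.timecourses, dtype=float)
        if tc.ndim != 2:
            raise ValueError("timecourses must be components x volumes")
        if tc.shape[1] < 10:
            raise ValueError("need at least 10 volumes")
        if not np.all(np.isfinite(tc)):
            raise ValueError("non-finite time course values")
        self.timecourses = tc
        if not self.component_names:
            self.component_names = tuple(
                f"comp{i:02d}" for i in range(tc.shape[0])
            )

    @property
    def n_components(self) -> int:
        return self.timecourses.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.timecourses.shape[1]


@dataclass
class SortingResult:
    slopes: np.ndarray            # (n_subjects, K, n_components)
    subject_ids: tuple[str, ...]
    group_mean_slopes: dict[str, np.ndarray]   # group -> (K, n_components)
    z_map: dict[str, np.ndarray]               # group -> (K, n_components)
    flagged: dict[str, list[tuple[int, int]]]  # group -> [(state, comp)]
    z_threshold: float = 1.0


def hrf_kernel(dt: float, params: dict | None = None) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, unit sum."""
    p = dict(DEFAULT_HRF, **(params or {}))
    t = np.arange(0, p["length"] + dt, dt)
    peak = sstats.gamma.pdf(t, p["peak_delay"] / p["peak_disp"],
                            scale=p["peak_disp"])
    under = sstats.gamma.pdf(t, p["undershoot_delay"] / p["undershoot_disp"],
                             scale=p["undershoot_disp"])
    h = peak - under / p["undershoot_ratio"]
    return h / h.sum()


def build_regressors(
    seg: Segmentation,
    tr_s: float = 2.2,
    n_volumes: int = 270,
    hrf_params: dict | None = None,
    n_states: int | None = None,
    center: bool = True,
) -> np.ndarray:
    """HRF-convolved microstate regressors sampled at the volume times.

    Per state, the run onsets/durations define a 0/1 boxcar on a
    ``FINE_HZ`` grid spanning the scan; convolution with the canonical
    HRF and sampling at t = k * TR yields the (K, n_volumes) regressor
    matrix, mean-centered by default.
    """
    scan_s = n_volumes * tr_s
    if seg.n_samples / seg.fs < scan_s - 1.0 / seg.fs:
        raise ValueError("segmentation shorter than the fMRI scan")
    K = n_states if n_states is not None else int(seg.labels.max()) + 1
    dt = 1.0 / FINE_HZ
    n_fine = int(np.ceil(scan_s * FINE_HZ))
    # state active on the fine grid: nearest-preceding EEG sample
    src = np.minimum((np.arange(n_fine) * dt * seg.fs).astype(int),
                     seg.n_samples - 1)
    fine_labels = seg.labels[src]
    kernel = hrf_kernel(dt, hrf_params)
    vol_idx = np.minimum((np.arange(n_volumes) * tr_s * FINE_HZ).astype(int),
                         n_fine - 1)
    boxcars = (fine_labels[None, :] == np.arange(K)[:, None]).astype(float)
    conv = sps.fftconvolve(boxcars, kernel[None, :], axes=1)[:, :n_fine]
    # FFT round-off is ~1e-13 of the boxcar scale; harmless downstream
    regs = conv[:, vol_idx]
    if center:
        regs -= regs.mean(axis=1, keepdims=True)
    return regs


def sort_components(
    regs: np.ndarray, rsn: RSNTimecourseSet
) -> np.ndarray:
    """OLS slopes of each component time course on the K regressors.

    All K regressors compete in one multiple regression with an
    intercept; the returned matrix is (K, n_components).  If the design
    is rank-deficient the affected subject's slopes are returned as NaN.
    """
    K, n_vol = regs.shape
    if n_vol != rsn.n_volumes:
        raise ValueError("volume count mismatch between regressors and RSNs")
    X = np.column_stack([np.ones(n_vol), regs.T])
    if np.linalg.matrix_rank(X) < K + 1:
        return np.full((K, rsn.n_components), np.nan)
    beta, *_ = np.linalg.lstsq(X, rsn.timecourses.T, rcond=None)
    return beta[1:, :]  # drop intercept row


def aggregate_z(
    slopes: np.ndarray,
    subject_groups: list[str],
    subject_ids: list[str] | None = None,
    z_threshold: float = 1.0,
) -> SortingResult:
    """Group-average slopes and standardize across components.

    ``slopes`` is (n_subjects, K, n_components).  Within each
    (microstate, group) cell the group-mean slopes are standardized to
    Z-scores across the components (population standard deviation); a
    zero-variance cell yields an all-zero Z row.  Pairings with
    Z >= ``z_threshold`` are flagged — positive side only, mirroring the
    decision not to interpret negative couplings.
    """
    slopes = np.asarray(slopes, dtype=float)
    groups = np.asarray(subject_groups)
    ids = tuple(subject_ids) if subject_ids else tuple(
        f"s{i:02d}" for i in range(slopes.shape[0])
    )
    gms, zs, flags = {}, {}, {}
    for grp in sorted(set(groups.tolist())):
        sel = groups == grp
        if sel.sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 subjects")
        gm = np.nanmean(slopes[sel], axis=0)  # (K, n_components)
        z = np.zeros_like(gm)
        for k in range(gm.shape[0]):
            sd = gm[k].std()
            if sd > 0:
                z[k] = (gm[k] - gm[k].mean()) / sd
        gms[grp] = gm
        zs[grp] = z
        flags[grp] = [
            (int(k), int(c))
            for k in range(z.shape[0])
            for c in np.flatnonzero(z[k] >= z_threshold)
        ]
    return SortingResult(
        slopes=slopes,
        subject_ids=ids,
        group_mean_slopes=gms,
        z_map=zs,
        flagged=flags,
        z_threshold=z_threshold,
    )


def z_map_table(result: SortingResult,
                state_labels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Long-format Z-map table: group, state, component, mean slope, Z, flag."""
    rows = []
    for grp, z in result.z_map.items():
        K, n_comp = z.shape
        labels = state_labels or tuple(chr(ord("A") + i) for i in range(K))
        flagged = set(result.flagged[grp])
        for k in range(K):
            for c in range(n_comp):
                rows.append({
                    "group": grp,
                    "state": labels[k],
                    "component": c,
                    "mean_slope": result.group_mean_slopes[grp][k, c],
                    "z": z[k, c],
                    "flagged": (k, c) in flagged,
                })
    return pd.DataFrame(rows)
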
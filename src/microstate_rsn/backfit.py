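"""Competitive backfitting and temporal microstate statistics.

Each EEG sample is labeled with the template of highest absolute
spatial correlation; run-length statistics of the resulting label
sequence are the temporal parameters compared between groups: mean
duration (ms), occurrence (runs/s), ratio of total time, per-state GEV
and the sample-to-sample transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import TemplateSet
from .gfp import GFPSeries, average_reference
from .io_formats import EEGRecording


@dataclass
class Segmentation:
    """Per-sample microstate labels with the winning |correlation|."""

    labels: np.ndarray
    corr: np.ndarray
    fs: float
    subject_id: str = "s00"
    group: str = "control"

    @property
    def n_samples(self) -> int:
        return self.labels.size


@dataclass
class MicrostateMetrics:
    """Per-subject temporal statistics, one entry per microstate class."""

    mean_duration_ms: np.ndarray
    occurrence_per_s: np.ndarray
    ratio_total_time: np.ndarray
    gev: np.ndarray
    transition_matrix: np.ndarray          # sample-to-sample, diagonal included
    transition_matrix_runs: np.ndarray     # run-to-run, diagonal excluded
    subject_id: str = "s00"
    group: str = "control"
    unvisited: tuple[int, ...] = field(default_factory=tuple)

    @property
    def K(self) -> int:
        return self.mean_duration_ms.size

    def to_frame(self, labels: tuple[str, ...] | None = None) -> pd.DataFrame:
        labels = labels or tuple(chr(ord("A") + i) for i in range(self.K))
        return pd.DataFrame({
            "subject_id": self.subject_id,
            "group": self.group,
            "state": labels,
            "mean_duration_ms": self.mean_duration_ms,
            "occurrence_per_s": self.occurrence_per_s,
            "ratio_total_time": self.ratio_total_time,
            "gev": self.gev,
        })


def backfit(
    rec: EEGRecording,
    templates: TemplateSet,
    gfp_floor_frac: float = 0.5,
) -> Segmentation:
    """Label every sample with the template of highest |spatial correlation|.

    Ties break toward the lowest template index.  Samples whose GFP is
    below ``gfp_floor_frac`` of the median GFP carry no usable
    topography (noise dominates) and inherit the previous label; a
    leading low-GFP stretch takes the first valid label.
    """
    if rec.data.shape[0] != templates.n_channels:
        raise ValueError("channel count mismatch between recording and templates")
    x = average_reference(rec.data)
    norms = np.linalg.norm(x, axis=0)
    gfp = norms / np.sqrt(x.shape[0])
    safe = np.where(norms > 0, norms, 1.0)
    u = x / safe
    corr = templates.templates @ u  # (K, n_samples)
    labels = np.argmax(np.abs(corr), axis=0)
    best = np.abs(corr[labels, np.arange(labels.size)])
    best[norms == 0] = 0.0

    floor = gfp_floor_frac * np.median(gfp)
    low = gfp < floor
    if low.any() and not low.all():
        valid = np.flatnonzero(~low)
        # inherit previous valid label; leading low samples take first valid
        idx = np.searchsorted(valid, np.arange(labels.size), side="right") - 1
        idx = np.clip(idx, 0, valid.size - 1)
        labels = labels[valid[idx]]
    return Segmentation(labels=labels, corr=best, fs=rec.fs,
                        subject_id=rec.subject_id, group=rec.group)


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode: (state per run, run length, run start index)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return (np.empty(0, dtype=int),) * 3
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    lengths = np.diff(np.concatenate([starts, [labels.size]]))
    return labels[starts], lengths, starts


def compute_metrics(
    seg: Segmentation,
    g: GFPSeries | None = None,
    templates: TemplateSet | None = None,
    K: int | None = None,
    trim_edges: bool = False,
) -> MicrostateMetrics:
    """Temporal statistics of a segmentation.

    ``trim_edges`` drops the first and last run (whose true extent is
    censored by the recording boundaries) before computing durations,
    occurrence and coverage; on trimmed sequences the identity
    mean_duration_s * occurrence_per_s == ratio_total_time is exact.
    Per-state GEV needs the GFP series; it is GFP-weighted over all
    samples of the full sequence.  Transition matrices always use the
    full sequence.
    """
    if K is None:
        K = templates.K if templates is not None else int(seg.labels.max()) + 1
    labels = seg.labels
    if labels.size < 2:
        raise ValueError("segmentation too short for metrics")

    states, lengths, starts = run_lengths(labels)
    # sample-to-sample transition matrix, diagonal included
    trans = np.zeros((K, K))
    np.add.at(trans, (labels[:-1], labels[1:]), 1.0)
    row = trans.sum(axis=1, keepdims=True)
    unvisited = tuple(int(k) for k in range(K) if row[k, 0] == 0)
    trans = np.divide(trans, row, out=np.full_like(trans, 1.0 / K), where=row > 0)
    # run-to-run matrix, diagonal excluded by construction
    trans_runs = np.zeros((K, K))
    if states.size > 1:
        np.add.at(trans_runs, (states[:-1], states[1:]), 1.0)
    rrow = trans_runs.sum(axis=1, keepdims=True)
    trans_runs = np.divide(
        trans_runs, rrow, out=np.zeros_like(trans_runs), where=rrow > 0
    )

    if trim_edges and states.size > 2:
        states_d, lengths_d = states[1:-1], lengths[1:-1]
    else:
        states_d, lengths_d = states, lengths
    total = lengths_d.sum()
    duration = np.zeros(K)
    occurrence = np.zeros(K)
    rtt = np.zeros(K)
    for k in range(K):
        sel = states_d == k
        n_runs = int(sel.sum())
        if n_runs:
            duration[k] = lengths_d[sel].mean() * 1000.0 / seg.fs
            occurrence[k] = n_runs / (total / seg.fs)
            rtt[k] = lengths_d[sel].sum() / total

    gev = np.zeros(K)
    if g is not None and templates is not None:
        gv = np.asarray(g.values)
        if gv.size != labels.size:
            raise ValueError("GFP series length does not match segmentation")
        contrib = (gv * seg.corr) ** 2
        denom = float(np.sum(gv**2))
        for k in range(K):
            gev[k] = contrib[labels == k].sum() / denom

    return MicrostateMetrics(
        mean_duration_ms=duration,
        occurrence_per_s=occurrence,
        ratio_total_time=rtt,
        gev=gev,
        transition_matrix=trans,
        transition_matrix_runs=trans_runs,
        subject_id=seg.subject_id,
        group=seg.group,
        unvisited=unvisited,
    )


def metrics_table(metrics: list[MicrostateMetrics],
                  labels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Long-format table of per-subject metrics, one row per subject x state."""
    return pd.concat([m.to_frame(labels) for m in metrics], ignore_index=True)
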
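"""Interpretable vascular descriptors from barcodes and networks.

Topological descriptors (from the radial and alpha filtrations):

* **topological tortuosity** — a tortuous vessel intersects the growing
  sphere repeatedly and sheds many small connected components that quickly
  merge back; the descriptor is the number of short dimension-0 bars
  (persistence <= 10% of the maximal radius by default) divided by the
  number of vessel segments. The normalization makes the measure comparable
  across networks of different size.
* **loops per segment** — the number of dimension-1 bars of the radial
  filtration divided by the number of vessel segments.
* **void descriptor** — the median persistence of dimension-2 bars of the
  alpha filtration; bar length is a proxy for avascular-region volume.

Standard comparator metrics:

* **clr** (chord-length ratio) — Euclidean distance between a segment's
  termini divided by its path length; 1 for a straight vessel, toward 0 for
  a tortuous one.
* **SOAM** (sum-of-angles metric) — total angle between consecutive
  chord tangents of the segment resampled at uniform arc length, in
  degrees; 0 for a straight vessel. A per-length variant (degrees/um) is
  reported alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .network import VesselNetwork, summarize
from .persistence import Barcode

logger = logging.getLogger(__name__)


def topological_tortuosity(bc0: Barcode, n_segments: int,
                           short_fraction: float = 0.1,
                           include_zero_bars: bool = False) -> float:
    """Short dimension-0 bars per vessel segment.

    A bar is short when its persistence is <= ``short_fraction`` times the
    final filtration radius (inclusive). Zero-persistence bars — nodes that
    enter and merge at the same radius step — are excluded by default, since
    under the half-open convention ``[b, b)`` is empty; pass
    ``include_zero_bars=True`` to count them.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    cutoff = short_fraction * bc0.end_value
    pers = bc0.persistences(dim=0)
    short = (pers <= cutoff) if include_zero_bars else \
        (pers > 0) & (pers <= cutoff)
    return float(short.sum()) / n_segments


def loops_per_segment(bc1: Barcode, n_segments: int) -> float:
    """Number of dimension-1 bars divided by the number of vessel segments."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    return bc1.n_bars(dim=1) / n_segments


def void_descriptor(bc2: Barcode, min_persistence_rel: float = 1e-9) -> float:
    """Median persistence of dimension-2 bars (square micrometers).

    Bars with persistence below ``min_persistence_rel`` times the final
    filtration value are numerical artifacts of nearly co-spherical points
    and are excluded. Returns 0 (with a warning) when no dimension-2 bars
    remain.
    """
    pers = bc2.persistences(dim=2)
    pers = pers[pers > min_persistence_rel * max(bc2.end_value, 1.0)]
    if len(pers) == 0:
        logger.warning("no dimension-2 bars; void descriptor reported as 0")
        return 0.0
    return float(np.median(pers))


# ---------------------------------------------------------------------------
# single-vessel tortuosity metrics


def clr(polyline) -> float:
    """Chord-length ratio of a vessel polyline: endpoint distance over path
    length, in (0, 1]; 0 for a closed self-loop."""
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("polyline must contain at least 2 points")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(steps.sum())
    if length <= 0:
        raise ValueError("polyline has zero path length")
    return float(np.linalg.norm(pts[-1] - pts[0]) / length)


@dataclass(frozen=True)
class SoamResult:
    total_degrees: float
    degrees_per_um: float


def soam(polyline, step: Optional[float] = None) -> SoamResult:
    """Sum-of-angles metric of a vessel polyline.

    The polyline is resampled at uniform arc length (default step: the
    median inter-point spacing); the angles between consecutive chord
    tangents are summed. Returns the raw sum in degrees together with the
    per-path-length variant. Degenerate inputs (fewer than 3 resampled
    points) score 0 with a warning.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("polyline must contain at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    length = float(seg.sum())
    if length <= 0:
        raise ValueError("polyline has zero path length")
    if step is None:
        step = float(np.median(seg[seg > 0]))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_samples = int(math.floor(length / step)) + 1
    if n_samples < 3:
        logger.warning("polyline too short for SOAM at step %.3g; scored 0",
                       step)
        return SoamResult(0.0, 0.0)
    targets = np.arange(n_samples) * step
    resampled = np.column_stack([np.interp(targets, arc, pts[:, k])
                                 for k in range(3)])
    tangents = np.diff(resampled, axis=0)
    norms = np.linalg.norm(tangents, axis=1)
    keep = norms > 0
    tangents, norms = tangents[keep], norms[keep]
    if len(tangents) < 2:
        logger.warning("degenerate polyline for SOAM; scored 0")
        return SoamResult(0.0, 0.0)
    cosines = np.einsum("ij,ij->i", tangents[:-1], tangents[1:]) / (
        norms[:-1] * norms[1:])
    angles = np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))
    total = float(angles.sum())
    return SoamResult(total, total / length)


# ---------------------------------------------------------------------------
# combined descriptor set


@dataclass
class DescriptorSet:
    """Per-network scalar summaries; absent inputs give ``None`` fields."""

    tortuosity_topological: Optional[float] = None
    n_loops: Optional[int] = None
    loops_per_segment: Optional[float] = None
    void_median_persistence: Optional[float] = None
    clr_mean: Optional[float] = None
    soam_mean: Optional[float] = None
    soam_per_um_mean: Optional[float] = None
    n_segments: Optional[int] = None
    n_branching_points: Optional[int] = None
    n_components: Optional[int] = None
    total_length: Optional[float] = None
    mean_segment_length: Optional[float] = None
    max_segment_length: Optional[float] = None
    mean_diameter: Optional[float] = None
    max_diameter: Optional[float] = None
    length_to_diameter: Optional[float] = None

    def to_dict(self) -> Dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorSet":
        row = df.iloc[0].to_dict()
        clean = {k: (None if pd.isna(v) else v) for k, v in row.items()
                 if k in {f.name for f in fields(cls)}}
        for key in ("n_loops", "n_segments", "n_branching_points",
                    "n_components"):
            if clean.get(key) is not None:
                clean[key] = int(clean[key])
        return cls(**clean)


def compute_all(net: VesselNetwork,
                bc0: Optional[Barcode] = None,
                bc1: Optional[Barcode] = None,
                bc2: Optional[Barcode] = None,
                short_fraction: float = 0.1,
                include_zero_bars: bool = False,
                soam_step: Optional[float] = None) -> DescriptorSet:
    """Populate every descriptor the provided inputs allow.

    ``bc0``/``bc1`` are barcodes of a radial filtration of ``net``; ``bc2``
    a barcode of an alpha filtration of its nodes. Fields whose inputs are
    missing are left ``None`` rather than silently zero.
    """
    summary = summarize(net)
    ds = DescriptorSet(**summary.to_dict())
    clrs, soams, soams_per = [], [], []
    for path in net.segments:
        pts = net.segment_coords(path)
        clrs.append(clr(pts))
        res = soam(pts, step=soam_step)
        soams.append(res.total_degrees)
        soams_per.append(res.degrees_per_um)
    if clrs:
        ds.clr_mean = float(np.mean(clrs))
        ds.soam_mean = float(np.mean(soams))
        ds.soam_per_um_mean = float(np.mean(soams_per))
    if bc0 is not None:
        ds.tortuosity_topological = topological_tortuosity(
            bc0, summary.n_segments, short_fraction, include_zero_bars)
    if bc1 is not None:
        ds.n_loops = bc1.n_bars(dim=1)
        ds.loops_per_segment = loops_per_segment(bc1, summary.n_segments)
    if bc2 is not None:
        ds.void_median_persistence = void_descriptor(bc2)
    return ds
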
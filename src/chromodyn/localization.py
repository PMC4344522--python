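"""Heterochromatin enrichment scoring and salt-extraction binding profiles.

Pericentromeric heterochromatin appears as dense DNA-stain foci in mouse
nuclei.  A protein's enrichment there is quantified as the ratio of its
mean intensity in one (randomly chosen) focus to its mean intensity in
three sampled nucleoplasmic areas; a homogeneously distributed protein
gives a ratio of 1.  Salt-extraction series are summarized as the percent
of signal remaining chromatin-bound (pellet) at each salt concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage import measure

__all__ = [
    "EnrichmentResult",
    "ExtractionProfile",
    "segment_foci",
    "enrichment_ratio",
    "score_nucleus",
    "summarize_enrichment",
    "percent_bound",
]


@dataclass(frozen=True)
class EnrichmentResult:
    nucleus_id: str
    focus_mean: float
    nucleoplasm_mean: float

    @property
    def ratio(self) -> float:
        return self.focus_mean / self.nucleoplasm_mean


@dataclass(frozen=True)
class ExtractionProfile:
    """Percent chromatin-bound at each salt concentration."""

    salt_mM: tuple[float, ...]
    pellet_signal: tuple[float, ...]
    sup_signal: tuple[float, ...]
    percent_bound: tuple[float, ...]   # nan where both signals are zero
    undefined: tuple[bool, ...]


def segment_foci(
    dna_channel: np.ndarray,
    nucleus_mask: np.ndarray,
    threshold_k: float = 2.0,
    min_area: int = 5,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Detect dense heterochromatin foci in the DNA channel.

    Foci are connected components of pixels brighter than mean + k*SD of
    the DNA signal within the nucleus; components smaller than ``min_area``
    pixels are discarded.  An empty result is valid (no foci).

    Returns ``(labels, centers)`` with labels a labeled mask (0 outside
    foci) and centers the (row, col) centroids.
    """
    dna = np.asarray(dna_channel, dtype=float)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    inside = dna[nucleus_mask]
    threshold = inside.mean() + threshold_k * inside.std()
    candidate = (dna > threshold) & nucleus_mask
    labels = measure.label(candidate)
    centers: list[tuple[float, float]] = []
    keep = np.zeros_like(labels)
    next_id = 1
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            keep[labels == region.label] = next_id
            centers.append(tuple(region.centroid))
            next_id += 1
    return keep, centers


def _sample_nucleoplasm_disks(
    nucleus_mask: np.ndarray,
    exclude: np.ndarray,
    radius: float,
    n_disks: int,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Three (by default) random disks inside the nucleus avoiding foci."""
    # candidate centers: nucleus interior eroded so a disk fits inside
    struct = _disk_footprint(int(np.ceil(radius)))
    interior = ndimage.binary_erosion(nucleus_mask, structure=struct)
    coords = np.argwhere(interior)
    if len(coords) == 0:
        raise ValueError("nucleus too small for nucleoplasm disks of this radius")
    yy, xx = np.mgrid[: nucleus_mask.shape[0], : nucleus_mask.shape[1]]
    union = np.zeros_like(nucleus_mask)
    placed = 0
    for _ in range(max_attempts):
        if placed == n_disks:
            break
        cy, cx = coords[rng.integers(len(coords))]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2
        if not (disk & exclude).any():
            union |= disk
            placed += 1
    if placed < n_disks:
        raise ValueError("could not place nucleoplasm disks away from foci")
    return union


def _disk_footprint(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    return yy ** 2 + xx ** 2 <= r ** 2


def enrichment_ratio(
    protein_channel: np.ndarray,
    focus_mask: np.ndarray,
    nucleoplasm_mask: np.ndarray,
    nucleus_id: str = "0",
) -> EnrichmentResult:
    """Mean protein intensity in the focus divided by the mean over the
    sampled nucleoplasm regions.  The two region sets must be disjoint."""
    protein = np.asarray(protein_channel, dtype=float)
    focus_mask = np.asarray(focus_mask, dtype=bool)
    nucleoplasm_mask = np.asarray(nucleoplasm_mask, dtype=bool)
    if not focus_mask.any():
        raise ValueError("no focus")
    if not nucleoplasm_mask.any():
        raise ValueError("no nucleoplasm sample")
    if (focus_mask & nucleoplasm_mask).any():
        raise ValueError("focus and nucleoplasm samples overlap")
    return EnrichmentResult(
        nucleus_id=nucleus_id,
        focus_mean=float(protein[focus_mask].mean()),
        nucleoplasm_mean=float(protein[nucleoplasm_mask].mean()),
    )


def score_nucleus(
    dna_channel: np.ndarray,
    protein_channel: np.ndarray,
    nucleus_mask: np.ndarray,
    seed: int = 0,
    threshold_k: float = 2.0,
    n_nucleoplasm_disks: int = 3,
    nucleus_id: str = "0",
) -> EnrichmentResult:
    """Full per-nucleus scoring: segment foci in the DNA channel, pick one
    focus at random (seeded), sample three nucleoplasm disks of the same
    radius away from all foci, and compute the enrichment ratio."""
    rng = np.random.default_rng(seed)
    labels, _ = segment_foci(dna_channel, nucleus_mask, threshold_k=threshold_k)
    ids = np.unique(labels[labels > 0])
    if len(ids) == 0:
        raise ValueError("no focus")
    chosen = int(rng.choice(ids))
    focus = labels == chosen
    radius = float(np.sqrt(focus.sum() / np.pi))
    nucleoplasm = _sample_nucleoplasm_disks(
        np.asarray(nucleus_mask, dtype=bool), labels > 0, radius,
        n_nucleoplasm_disks, rng,
    )
    return enrichment_ratio(protein_channel, focus, nucleoplasm, nucleus_id=nucleus_id)


def summarize_enrichment(
    group_a: Sequence[float], group_b: Sequence[float]
) -> dict:
    """Group means +/- SD and a Welch two-sample p-value.

    A singleton group gets a mean but no test.  When both groups are
    constant and equal the p-value is 1 by policy.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs >=1 ratio")
    out = {
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        "n_a": len(a), "n_b": len(b),
    }
    if len(a) < 2 or len(b) < 2:
        out["p"] = None
        return out
    if a.std() == 0 and b.std() == 0:
        out["p"] = 1.0 if a.mean() == b.mean() else 0.0
        return out
    _, p = stats.ttest_ind(a, b, equal_var=False)
    out["p"] = float(p)
    return out


def percent_bound(
    salt_mM: Sequence[float],
    pellet_signal: Sequence[float],
    sup_signal: Sequence[float],
) -> ExtractionProfile:
    """Percent bound to chromatin = 100 * pellet / (pellet + sup) at each
    salt concentration.  A concentration where both signals are zero gets
    a NaN entry and is flagged, not raised.  Monotonicity in salt is not
    enforced."""
    salt = tuple(float(s) for s in salt_mM)
    pellet = np.asarray(pellet_signal, dtype=float)
    sup = np.asarray(sup_signal, dtype=float)
    if not (len(salt) == len(pellet) == len(sup)):
        raise ValueError("signals must align with salt concentrations")
    if np.any(pellet < 0) or np.any(sup < 0):
        raise ValueError("signals must be non-negative")
    total = pellet + sup
    undefined = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(undefined, np.nan, 100.0 * pellet / total)
    return ExtractionProfile(
        salt_mM=salt,
        pellet_signal=tuple(float(x) for x in pellet),
        sup_signal=tuple(float(x) for x in sup),
        percent_bound=tuple(float(x) for x in pct),
        undefined=tuple(bool(u) for u in undefined),
    )
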
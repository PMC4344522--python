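"""Seeded generators for every synthetic input the analysis stages consume.

The generators emulate the statistical structure each quantification stage
assumes:

* FRAP traces and movies: single-exponential recovery of a mobile pool on
  top of an immobile pool, acquisition photobleaching of the whole nucleus,
  the bleach-event drop of total nuclear signal, stage drift and
  multiplicative Gaussian noise.
* Two-channel nucleus images: DNA channel with dense heterochromatin-like
  foci, protein channel with a planted focus/nucleoplasm enrichment ratio.
* Genotype cohorts: multinomial Mendelian draws thinned by genotype-specific
  survival, with a sex split for the homozygous-null class.
* Two-group expression matrices with planted fold-changes in triplicate.
* Tripartite linker-histone-like protein sequences (NTD, three globular
  domains, an acidic D/E tract, a basic CTD) with an optionally planted
  P-x-V-x-L motif.

All randomness flows through one ``numpy`` generator constructed from the
explicit ``seed`` argument; identical (spec, seed) pairs give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .frap import IntensityTrace
from .genetics import GenotypeCounts, counts_from_ratio

__all__ = [
    "KineticParams",
    "AcquisitionParams",
    "NucleusImageSpec",
    "CohortSpec",
    "ExpressionSimSpec",
    "Region",
    "ProteinSimSpec",
    "simulate_frap_traces",
    "simulate_frap_movie",
    "simulate_nucleus_pair",
    "simulate_genotype_cohort",
    "simulate_expression",
    "simulate_protein",
    "recovery_curve",
    "hp1bp3_like_layout",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Two-state FRAP kinetics of a nuclear protein.

    tau_half
        half-time of recovery of the mobile pool, seconds; the recovery
        rate is k = ln 2 / tau_half.
    immobile_fraction
        fraction of the pool that does not exchange on the experiment's
        timescale.
    bleach_depth
        normalized ROI intensity immediately post-bleach (the f0 of the
        fully normalized curve).
    acq_bleach_rate
        fractional whole-cell signal loss per acquired frame.
    noise_sd
        relative (multiplicative) Gaussian noise on intensities.
    """

    tau_half: float = 14.1
    immobile_fraction: float = 0.128
    bleach_depth: float = 0.3
    acq_bleach_rate: float = 0.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not self.tau_half > 0:
            raise ValueError("tau_half must be positive")
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must be in [0,1]")
        if not 0.0 <= self.bleach_depth < 1.0:
            raise ValueError("bleach_depth must be in [0,1)")
        if self.acq_bleach_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")

    @property
    def rate(self) -> float:
        return float(np.log(2) / self.tau_half)


@dataclass(frozen=True)
class AcquisitionParams:
    """Frame counts and timing of a FRAP series (10 pre + 180 post at 1 s
    or 250 ms are the typical slow/fast settings)."""

    n_prebleach: int = 10
    n_postbleach: int = 180
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.n_prebleach < 5:
            raise ValueError("need >=5 pre-bleach frames (normalization reference)")
        if self.n_postbleach < 1:
            raise ValueError("need >=1 post-bleach frame")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")


@dataclass(frozen=True)
class NucleusImageSpec:
    """A circular nucleus with intensity-enriched foci in two channels."""

    image_size: int = 128
    nucleus_radius: int = 48
    n_foci: int = 4
    focus_radius: int = 6
    enrichment: float = 3.0          # focus / nucleoplasm mean in the protein channel
    base_intensity: float = 100.0
    noise_sd: float = 0.0            # absolute Gaussian noise
    dna_focus_contrast: float = 3.0  # focus / nucleoplasm mean in the DNA channel

    def __post_init__(self) -> None:
        if self.enrichment < 0:
            raise ValueError("enrichment must be >=0")
        if self.n_foci < 0:
            raise ValueError("n_foci must be >=0")
        if self.n_foci > 0 and self.focus_radius >= self.nucleus_radius:
            raise ValueError("foci must fit fully inside the nucleus")
        if 2 * self.nucleus_radius >= self.image_size:
            raise ValueError("nucleus must fit inside the image")


@dataclass(frozen=True)
class CohortSpec:
    """A heterozygote-intercross cohort with genotype-specific survival."""

    n_total_pups: int = 784
    expected_ratio: tuple[float, float, float] = (1.0, 2.0, 1.0)
    survival_by_genotype: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sex_ratio_ko: float = 0.5        # fraction male among surviving -/- pups
    labels: tuple[str, str, str] = ("+/+", "+/-", "-/-")

    def __post_init__(self) -> None:
        if self.n_total_pups < 1:
            raise ValueError("need >=1 pup")
        if all(r == 0 for r in self.expected_ratio):
            raise ValueError("expected_ratio must not be all zero")
        if any(not 0 <= s <= 1 for s in self.survival_by_genotype):
            raise ValueError("survival fractions must be in [0,1]")
        if not 0 <= self.sex_ratio_ko <= 1:
            raise ValueError("sex_ratio_ko must be in [0,1]")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Two-group expression matrix (log2 scale) with planted fold-changes."""

    n_genes: int = 20_000
    n_up: int = 271
    n_down: int = 112
    fold_range: tuple[float, float] = (1.6, 2.5)
    replicates_per_group: int = 3
    noise_sd: float = 0.08           # log2-scale residual sd (high-quality triplicates)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down must not exceed n_genes")
        if self.replicates_per_group < 2:
            raise ValueError("need >=2 replicates per group")
        if not self.fold_range[0] > 1:
            raise ValueError("fold_range lower bound must exceed 1")
        if self.fold_range[1] < self.fold_range[0]:
            raise ValueError("fold_range must be increasing")


@dataclass(frozen=True)
class Region:
    """A named protein region with a target residue composition.

    ``composition`` maps residues to target fractions; residues not listed
    share the remaining probability mass uniformly.
    """

    name: str
    length: int
    composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("region length must be >=1")
        bad = set(self.composition) - set(AA_ALPHABET)
        if bad:
            raise ValueError(f"non-standard residues in composition: {sorted(bad)}")
        if sum(self.composition.values()) > 1.0 + 1e-9:
            raise ValueError("composition fractions must sum to <=1")


def hp1bp3_like_layout() -> tuple[Region, ...]:
    """Default 553-residue tripartite layout: a Glu-rich NTD, three H1-like
    globular domains, a pure D/E acidic tract and a basic (40% K/R) CTD."""
    return (
        Region("NTD", 157, {"E": 0.20, "S": 0.10, "T": 0.08, "P": 0.08, "K": 0.10, "A": 0.10}),
        Region("GD1", 76, {"K": 0.12, "A": 0.10, "L": 0.08, "S": 0.08, "G": 0.06, "E": 0.05, "T": 0.05}),
        Region("GD2", 80, {"K": 0.12, "A": 0.10, "L": 0.08, "S": 0.08, "G": 0.06, "E": 0.05, "T": 0.05}),
        Region("GD3", 80, {"K": 0.12, "A": 0.10, "L": 0.08, "S": 0.08, "G": 0.06, "E": 0.05, "T": 0.05}),
        Region("DE", 20, {"D": 0.5, "E": 0.5}),
        Region("CTD", 140, {"K": 0.28, "R": 0.12, "A": 0.15, "T": 0.10, "S": 0.10,
                            "P": 0.08, "V": 0.05, "G": 0.05, "E": 0.04, "Q": 0.03}),
    )


@dataclass(frozen=True)
class ProteinSimSpec:
    """A tripartite linker-histone-like protein with an optional planted
    P-x-V-x-L motif (default: PQVKL at residues 255-259)."""

    region_layout: tuple[Region, ...] = field(default_factory=hp1bp3_like_layout)
    motif_position: int | None = 255     # 1-based start, or None
    motif: str = "PQVKL"

    def __post_init__(self) -> None:
        if self.motif_position is not None:
            m = self.motif
            if len(m) != 5 or m[0] != "P" or m[2] != "V" or m[4] != "L":
                raise ValueError("planted motif must match P-x-V-x-L")
            start = self.motif_position
            end = start + len(m) - 1
            pos = 1
            inside = False
            for region in self.region_layout:
                if start >= pos and end <= pos + region.length - 1:
                    inside = True
                    break
                pos += region.length
            if not inside:
                raise ValueError("motif_position conflicts with region boundaries")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.region_layout)


# ---------------------------------------------------------------------------
# FRAP trace generator
# ---------------------------------------------------------------------------

def recovery_curve(t: np.ndarray, kin: KineticParams) -> np.ndarray:
    """Noise-free normalized recovery F(t) = b + m (1-b)(1 - exp(-k t))."""
    b = kin.bleach_depth
    m = 1.0 - kin.immobile_fraction
    return b + m * (1.0 - b) * (1.0 - np.exp(-kin.rate * np.asarray(t, dtype=float)))


def simulate_frap_traces(
    kin: KineticParams,
    acq: AcquisitionParams = AcquisitionParams(),
    n_nuclei: int = 1,
    seed: int = 0,
    roi_area_fraction: float = 0.1,
    base_intensity: float = 1000.0,
) -> list[IntensityTrace]:
    """Raw intensity traces whose double-normalized expectation is the
    closed-form recovery curve.

    The whole-nucleus channel decays by ``acq_bleach_rate`` per acquired
    frame and drops at the bleach event by the bleached fraction of total
    signal, (ROI area / nucleus area) * (1 - raw bleach factor); the raw
    bleach factor is chosen so that the *normalized* intensity immediately
    post-bleach equals ``kin.bleach_depth``.  The bleach frame itself is
    never emitted: t = 0 is the first post-bleach frame.
    """
    if n_nuclei < 1:
        raise ValueError("need >=1 nucleus")
    if not 0 < roi_area_fraction < 1:
        raise ValueError("roi_area_fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    a = roi_area_fraction
    beta = kin.bleach_depth
    # raw (physical) ROI bleach factor and the resulting total-signal drop
    b_raw = beta * (1.0 - a) / (1.0 - a * beta)
    drop = 1.0 - a * (1.0 - b_raw)
    decay = 1.0 - kin.acq_bleach_rate

    dt = acq.frame_interval
    pre_frames = np.arange(acq.n_prebleach)
    post_frames = acq.n_prebleach + 1 + np.arange(acq.n_postbleach)  # bleach frame skipped
    pre_times = (pre_frames - acq.n_prebleach - 1) * dt              # last pre at -2 dt
    post_times = np.arange(acq.n_postbleach) * dt
    model = recovery_curve(post_times, kin)

    traces = []
    for i in range(n_nuclei):
        roi = np.concatenate([
            base_intensity * decay ** pre_frames,
            base_intensity * decay ** post_frames * model * drop,
        ])
        nuc = np.concatenate([
            base_intensity * decay ** pre_frames,
            base_intensity * decay ** post_frames * drop,
        ])
        if kin.noise_sd > 0:
            roi = roi * (1.0 + kin.noise_sd * rng.standard_normal(roi.shape))
            nuc = nuc * (1.0 + kin.noise_sd * rng.standard_normal(nuc.shape))
        phase = np.array(["pre"] * acq.n_prebleach + ["post"] * acq.n_postbleach,
                         dtype=object)
        traces.append(IntensityTrace(
            times=np.concatenate([pre_times, post_times]),
            roi_mean=roi, nucleus_mean=nuc, phase=phase, nucleus_id=str(i),
        ))
    return traces


# ---------------------------------------------------------------------------
# FRAP movie generator
# ---------------------------------------------------------------------------

def _disk_mask(size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def simulate_frap_movie(
    kin: KineticParams,
    acq: AcquisitionParams = AcquisitionParams(n_prebleach=5, n_postbleach=40),
    drift_per_frame: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    image_size: int = 64,
    nucleus_radius: int = 24,
    roi_radius: int = 8,
    base_intensity: float = 1000.0,
) -> dict:
    """A FRAP image stack with ground truth, for exercising registration.

    The nucleus is a uniform disk; the bleach region a smaller disk inside
    it.  Post-bleach pixel intensities follow a well-mixed two-state model:
    the immobile pool stays where it was bleached while the mobile pool
    equilibrates at rate k, conserving total fluorescence (up to acquisition
    photobleaching).  The whole field drifts by ``drift_per_frame`` (row,
    col) pixels each frame; masks and ROI are reported in frame-0
    coordinates.  The stack includes the bleach frame at index
    ``n_prebleach`` (to be dropped by trace extraction).

    Returns a dict with ``stack``, ``nucleus_mask``, ``roi_mask``,
    ``shifts`` (applied cumulative per-frame shifts) and ``params``.
    """
    rng = np.random.default_rng(seed)
    n_frames = acq.n_prebleach + 1 + acq.n_postbleach
    center0 = (image_size / 2.0, image_size / 2.0)
    drift = np.asarray(drift_per_frame, dtype=float)
    shifts = np.outer(np.arange(n_frames), drift)
    # nucleus must stay inside the frame at the final drifted position
    final = np.asarray(center0) + shifts[-1]
    if (final - nucleus_radius < 0).any() or (final + nucleus_radius >= image_size).any():
        raise ValueError("drift pushes the nucleus outside the frame")

    a = (roi_radius / nucleus_radius) ** 2
    beta = kin.bleach_depth
    b_raw = beta * (1.0 - a) / (1.0 - a * beta)
    drop = 1.0 - a * (1.0 - b_raw)
    decay = 1.0 - kin.acq_bleach_rate
    m = 1.0 - kin.immobile_fraction
    k = kin.rate
    dt = acq.frame_interval
    roi_offset = (0.0, nucleus_radius / 2.0)  # bleach spot off-center in the nucleus

    stack = np.zeros((n_frames, image_size, image_size), dtype=float)
    for f in range(n_frames):
        c = (center0[0] + shifts[f, 0], center0[1] + shifts[f, 1])
        nuc = _disk_mask(image_size, c, nucleus_radius)
        roi = _disk_mask(image_size, (c[0] + roi_offset[0], c[1] + roi_offset[1]), roi_radius)
        frame = np.zeros((image_size, image_size), dtype=float)
        if f < acq.n_prebleach:
            frame[nuc] = base_intensity
        else:
            t = max(0.0, (f - acq.n_prebleach - 1) * dt)
            mix = 1.0 - np.exp(-k * t)
            inside = (1.0 - m) * b_raw + m * (b_raw + (drop - b_raw) * mix)
            outside = (1.0 - m) + m * (1.0 + (drop - 1.0) * mix)
            frame[nuc] = base_intensity * outside
            frame[nuc & roi] = base_intensity * inside
        frame *= decay ** f
        if kin.noise_sd > 0:
            frame *= 1.0 + kin.noise_sd * rng.standard_normal(frame.shape)
        stack[f] = frame

    nucleus_mask = _disk_mask(image_size, center0, nucleus_radius)
    roi_mask = _disk_mask(
        image_size, (center0[0] + roi_offset[0], center0[1] + roi_offset[1]), roi_radius
    )
    return {
        "stack": stack,
        "nucleus_mask": nucleus_mask,
        "roi_mask": roi_mask,
        "shifts": shifts,
        "params": {"kin": kin, "acq": acq, "bleach_frame_index": acq.n_prebleach},
    }


# ---------------------------------------------------------------------------
# two-channel nucleus images
# ---------------------------------------------------------------------------

def simulate_nucleus_pair(spec: NucleusImageSpec, seed: int = 0) -> dict:
    """A two-channel nucleus image: DNA channel with dense foci, protein
    channel with the planted focus/nucleoplasm enrichment ratio.

    Returns ``dna``, ``protein``, ``nucleus_mask``, ``focus_labels``
    (labeled mask, 0 = background) and ``focus_centers`` (ground truth).
    """
    rng = np.random.default_rng(seed)
    size = spec.image_size
    center = (size / 2.0, size / 2.0)
    nucleus = _disk_mask(size, center, spec.nucleus_radius)

    centers: list[tuple[float, float]] = []
    max_offset = spec.nucleus_radius - spec.focus_radius - 1
    attempts = 0
    while len(centers) < spec.n_foci:
        attempts += 1
        if attempts > 1000 * max(spec.n_foci, 1):
            raise RuntimeError("could not place non-overlapping foci; too crowded")
        r = max_offset * np.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        cand = (center[0] + r * np.sin(theta), center[1] + r * np.cos(theta))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) > 2.5 * spec.focus_radius
               for c in centers):
            centers.append(cand)

    focus_labels = np.zeros((size, size), dtype=int)
    for i, c in enumerate(centers, start=1):
        focus_labels[_disk_mask(size, c, spec.focus_radius)] = i
    foci = focus_labels > 0

    dna = np.zeros((size, size), dtype=float)
    dna[nucleus] = spec.base_intensity
    dna[foci] = spec.base_intensity * spec.dna_focus_contrast
    protein = np.zeros((size, size), dtype=float)
    protein[nucleus] = spec.base_intensity
    protein[foci] = spec.base_intensity * spec.enrichment
    if spec.noise_sd > 0:
        dna[nucleus] += spec.noise_sd * rng.standard_normal(int(nucleus.sum()))
        protein[nucleus] += spec.noise_sd * rng.standard_normal(int(nucleus.sum()))

    return {
        "dna": dna,
        "protein": protein,
        "nucleus_mask": nucleus,
        "focus_labels": focus_labels,
        "focus_centers": centers,
    }


# ---------------------------------------------------------------------------
# genotype cohorts
# ---------------------------------------------------------------------------

def simulate_genotype_cohort(spec: CohortSpec, seed: int = 0) -> tuple[GenotypeCounts, dict]:
    """Draw a litter cohort multinomially from the expected Mendelian ratio,
    then thin each genotype binomially by its survival fraction.

    Returns the surviving ``GenotypeCounts`` plus a dict with the at-birth
    counts and the male/female split of the surviving third genotype.
    """
    rng = np.random.default_rng(seed)
    ratio = np.asarray(spec.expected_ratio, dtype=float)
    p = ratio / ratio.sum()
    born = rng.multinomial(spec.n_total_pups, p)
    surviving = np.array([
        rng.binomial(n, s) for n, s in zip(born, spec.survival_by_genotype)
    ])
    n_male_ko = int(rng.binomial(surviving[2], spec.sex_ratio_ko))
    gc = GenotypeCounts(
        labels=spec.labels,
        observed=tuple(int(x) for x in surviving),
        expected_ratio=spec.expected_ratio,
    )
    extra = {
        "born": tuple(int(x) for x in born),
        "ko_males": n_male_ko,
        "ko_females": int(surviving[2]) - n_male_ko,
    }
    return gc, extra


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def simulate_expression(spec: ExpressionSimSpec, seed: int = 0):
    """Two-group log2 expression matrix with planted fold-changes.

    Returns ``(matrix, truth)`` as pandas DataFrames: the matrix has genes
    as rows and samples ``a_1..a_n, b_1..b_n`` as columns; the truth table
    records each gene's planted direction ("up"/"down"/"null", group b
    relative to group a) and linear-scale fold.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n = spec.n_genes
    reps = spec.replicates_per_group
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)

    direction = np.array(["null"] * n, dtype=object)
    log2_shift = np.zeros(n)
    affected = rng.choice(n, size=spec.n_up + spec.n_down, replace=False)
    up_idx, down_idx = affected[: spec.n_up], affected[spec.n_up:]
    lo, hi = np.log2(spec.fold_range[0]), np.log2(spec.fold_range[1])
    log2_shift[up_idx] = rng.uniform(lo, hi, size=spec.n_up)
    log2_shift[down_idx] = -rng.uniform(lo, hi, size=spec.n_down)
    direction[up_idx] = "up"
    direction[down_idx] = "down"

    noise = rng.normal(0.0, spec.noise_sd, size=(n, 2 * reps))
    data = np.empty((n, 2 * reps))
    data[:, :reps] = baseline[:, None] + noise[:, :reps]
    data[:, reps:] = (baseline + log2_shift)[:, None] + noise[:, reps:]

    genes = [f"gene_{i:05d}" for i in range(n)]
    columns = [f"a_{j + 1}" for j in range(reps)] + [f"b_{j + 1}" for j in range(reps)]
    matrix = pd.DataFrame(data, index=genes, columns=columns)
    true_fold = np.where(log2_shift >= 0, 2.0 ** log2_shift, -(2.0 ** -log2_shift))
    truth = pd.DataFrame({"direction": direction, "true_fold": true_fold}, index=genes)
    return matrix, truth


# ---------------------------------------------------------------------------
# protein sequences
# ---------------------------------------------------------------------------

def _region_residues(region: Region, rng: np.random.Generator) -> list[str]:
    """Exact-count composition: residue counts apportioned by largest
    remainder from the target fractions, then shuffled within the region."""
    specified = list(region.composition.items())
    rest = [aa for aa in AA_ALPHABET if aa not in region.composition]
    leftover = 1.0 - sum(f for _, f in specified)
    shares = [f for _, f in specified] + [leftover / len(rest)] * len(rest) if rest else \
             [f for _, f in specified]
    letters = [aa for aa, _ in specified] + rest
    counts = counts_from_ratio(shares, region.length)
    residues = [aa for aa, c in zip(letters, counts) for _ in range(c)]
    return [residues[i] for i in rng.permutation(region.length)]


def simulate_protein(spec: ProteinSimSpec, seed: int = 0) -> tuple[str, list[tuple[str, int, int]]]:
    """Generate a protein sequence honoring the per-region composition
    targets, with the motif planted verbatim at ``motif_position`` if set.

    Returns ``(sequence, regions)`` where regions are (name, start, end)
    with 1-based inclusive coordinates.
    """
    rng = np.random.default_rng(seed)
    chars: list[str] = []
    regions: list[tuple[str, int, int]] = []
    pos = 1
    for region in spec.region_layout:
        chars.extend(_region_residues(region, rng))
        regions.append((region.name, pos, pos + region.length - 1))
        pos += region.length
    if spec.motif_position is not None:
        start = spec.motif_position - 1
        chars[start:start + len(spec.motif)] = list(spec.motif)
    return "".join(chars), regions
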
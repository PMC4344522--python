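"""End-to-end pipeline: simulate, analyze and report each requested stage.

A :class:`PipelineConfig` holds the global seed, the output directory and
one optional block per stage (frap, enrichment, genetics, expression,
seqfeat, phylo).  Every block is validated before any stage runs; the
report records the package version, a hash of the configuration and the
seed, so identical (config, seed) pairs give byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from . import expression as expr
from . import frap, genetics, localization, phylo, seqfeat, simkit
from .io import read_fasta, write_newick, write_traces_csv

logger = logging.getLogger("chromodyn")

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("frap", "enrichment", "genetics", "expression", "seqfeat", "phylo")


@dataclass(frozen=True)
class PipelineConfig:
    """Seed, output directory and per-stage parameter blocks."""

    seed: int = 0
    out_dir: str | None = None
    stages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, block in self.stages.items():
            if not isinstance(block, dict):
                raise ValueError(f"stage {name!r} block must be a mapping")
        _validate_blocks(self.stages)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        return cls(
            seed=int(data.pop("seed", 0)),
            out_dir=data.pop("out_dir", None),
            stages=data.pop("stages", data),
        )


def _validate_blocks(stages: dict) -> None:
    """Construct every stage's parameter objects up front so invalid
    settings fail before any stage runs."""
    if "frap" in stages:
        block = stages["frap"]
        simkit.KineticParams(**block.get("kinetics", {}))
        simkit.AcquisitionParams(**block.get("acquisition", {}))
        if block.get("n_nuclei", 12) < 1:
            raise ValueError("frap: n_nuclei must be >=1")
        if block.get("method", "interpolated") not in ("interpolated", "exponential_fit"):
            raise ValueError("frap: unknown fit method")
    if "enrichment" in stages:
        block = stages["enrichment"]
        simkit.NucleusImageSpec(**block.get("image", {}))
        if block.get("n_nuclei", 20) < 1:
            raise ValueError("enrichment: n_nuclei must be >=1")
    if "genetics" in stages:
        block = stages["genetics"]
        ratio = block.get("ratio", (3.5, 5.8, 1.0))
        total = block.get("total", 784)
        genetics.GenotypeCounts.from_ratio(ratio, total,
                                           expected_ratio=block.get("expected", (1, 2, 1)))
    if "expression" in stages:
        block = stages["expression"]
        simkit.ExpressionSimSpec(**block.get("sim", {}))
        if not block.get("min_fold", 1.4) > 1:
            raise ValueError("expression: min_fold must exceed 1")
        if not 0 < block.get("max_q", 0.1) <= 1:
            raise ValueError("expression: max_q must be in (0,1]")
    if "seqfeat" in stages:
        simkit.ProteinSimSpec(**stages["seqfeat"].get("sim", {}))
    if "phylo" in stages:
        block = stages["phylo"]
        if "alignment" not in block:
            raise ValueError("phylo: needs an 'alignment' FASTA path")
        if block.get("n_reps", 1000) < 1:
            raise ValueError("phylo: n_reps must be >=1")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and return (and optionally write) a
    machine-readable report.  A stage failure halts the run with the
    failing stage named; earlier stage outputs are retained in the
    partially written report."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps({"seed": config.seed, "stages": config.stages},
                   sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash,
        "stages": {},
    }
    for name in _STAGES:
        if name not in config.stages:
            continue
        logger.info("running stage %s (seed=%d)", name, config.seed)
        try:
            runner = globals()[f"_run_{name}"]
            report["stages"][name] = runner(config.stages[name], config.seed, out_dir)
        except Exception as exc:
            report["error"] = {"stage": name, "message": str(exc)}
            if out_dir:
                _write_report(report, out_dir)
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    if out_dir:
        _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonable) + "\n",
        encoding="utf-8",
    )


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _run_frap(block: dict, seed: int, out_dir: Path | None) -> dict:
    kin = simkit.KineticParams(**block.get("kinetics", {}))
    acq = simkit.AcquisitionParams(**block.get("acquisition", {}))
    n_nuclei = int(block.get("n_nuclei", 12))
    method = block.get("method", "interpolated")
    traces = simkit.simulate_frap_traces(kin, acq, n_nuclei=n_nuclei, seed=seed)
    if out_dir:
        write_traces_csv(traces, out_dir / "frap_traces.csv")
    curves = [frap.normalize_trace(t) for t in traces]
    ensemble = frap.aggregate_curves(curves)
    mean_summary = frap.fit_recovery(ensemble, method=method)
    per_nucleus = [frap.fit_recovery(c, method=method) for c in curves]
    taus = [s.tau_half for s in per_nucleus if s.tau_half is not None]
    return {
        "n_nuclei": n_nuclei,
        "method": method,
        "mean_curve": {
            "tau_half_s": mean_summary.tau_half,
            "immobile_fraction": mean_summary.immobile_fraction,
            "mobile_fraction": mean_summary.mobile_fraction,
            "plateau": mean_summary.plateau,
            "f0": mean_summary.f0,
        },
        "per_nucleus": {
            "tau_half_mean_s": float(np.mean(taus)) if taus else None,
            "tau_half_sem_s": float(np.std(taus, ddof=1) / np.sqrt(len(taus)))
            if len(taus) > 1 else None,
            "immobile_mean": float(np.mean([s.immobile_fraction for s in per_nucleus])),
        },
        "generating": {"tau_half_s": kin.tau_half, "immobile_fraction": kin.immobile_fraction},
    }


def _run_enrichment(block: dict, seed: int, out_dir: Path | None) -> dict:
    spec = simkit.NucleusImageSpec(**block.get("image", {}))
    n_nuclei = int(block.get("n_nuclei", 20))
    ratios = []
    for i in range(n_nuclei):
        sim = simkit.simulate_nucleus_pair(spec, seed=seed + i)
        res = localization.score_nucleus(
            sim["dna"], sim["protein"], sim["nucleus_mask"],
            seed=seed + i, nucleus_id=str(i),
        )
        ratios.append(res.ratio)
    return {
        "n_nuclei": n_nuclei,
        "planted_enrichment": spec.enrichment,
        "mean_ratio": float(np.mean(ratios)),
        "sd_ratio": float(np.std(ratios, ddof=1)) if n_nuclei > 1 else 0.0,
    }


def _run_genetics(block: dict, seed: int, out_dir: Path | None) -> dict:
    ratio = block.get("ratio", (3.5, 5.8, 1.0))
    total = int(block.get("total", 784))
    expected = tuple(block.get("expected", (1.0, 2.0, 1.0)))
    gc = genetics.GenotypeCounts.from_ratio(ratio, total, expected_ratio=expected)
    chi2 = genetics.mendelian_chi2(gc)
    deficit = genetics.survival_deficit(gc, genotype_index=2)
    out = {"counts": list(gc.observed), "total": gc.total,
           "chi2": chi2, "ko_deficit": deficit}
    if "ko_males" in block and "ko_females" in block:
        out["sex_ratio"] = genetics.sex_ratio_test(block["ko_males"], block["ko_females"])
    return out


def _run_expression(block: dict, seed: int, out_dir: Path | None) -> dict:
    spec = simkit.ExpressionSimSpec(**block.get("sim", {}))
    matrix, truth = simkit.simulate_expression(spec, seed=seed)
    labels = ["a"] * spec.replicates_per_group + ["b"] * spec.replicates_per_group
    result = expr.de_pipeline(matrix, labels,
                              min_fold=block.get("min_fold", 1.4),
                              max_q=block.get("max_q", 0.1))
    if out_dir:
        result["table"].to_csv(out_dir / "de_results.tsv", sep="\t")
    return {
        "n_genes": spec.n_genes,
        "planted_up": spec.n_up,
        "planted_down": spec.n_down,
        "n_up": result["n_up"],
        "n_down": result["n_down"],
        "min_fold": result["min_fold"],
        "max_q": result["max_q"],
    }


def _run_seqfeat(block: dict, seed: int, out_dir: Path | None) -> dict:
    spec = simkit.ProteinSimSpec(**block.get("sim", {}))
    seq, regions = simkit.simulate_protein(spec, seed=seed)
    hits = seqfeat.scan_pxvxl(seq)
    comps = seqfeat.composition_profile(seq, regions)
    tracts = seqfeat.find_acidic_tract(seq, min_len=block.get("min_tract_len", 15))
    return {
        "length": len(seq),
        "motif_hits": [{"start": h.start, "end": h.end, "seq": h.matched_sequence}
                       for h in hits],
        "acidic_tracts": [{"start": t.start, "end": t.end, "length": t.length}
                          for t in tracts],
        "composition": [{"region": c.name, "pct_basic": c.pct_basic,
                         "pct_acidic": c.pct_acidic, "pct_hydrophobic": c.pct_hydrophobic}
                        for c in comps],
    }


def _run_phylo(block: dict, seed: int, out_dir: Path | None) -> dict:
    aln = read_fasta(block["alignment"], aligned=True)
    gap_policy = block.get("gap_policy", "pairwise")
    support = phylo.bootstrap_support(
        aln, n_reps=int(block.get("n_reps", 1000)), seed=seed, gap_policy=gap_policy,
    )
    tree = support.tree
    if "outgroup" in block:
        tree = phylo.root_tree(tree, block["outgroup"])
    if out_dir:
        write_newick(tree, out_dir / "tree.nwk")
    return {
        "n_taxa": aln.n_taxa,
        "n_sites": aln.n_sites,
        "n_reps": support.n_reps,
        "n_discarded": support.n_discarded,
        "gap_policy": gap_policy,
        "supports": {"|".join(sorted(bp)): v for bp, v in support.supports.items()},
        "newick": tree.as_string(schema="newick", suppress_rooting=True).strip(),
    }
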
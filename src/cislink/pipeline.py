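"""End-to-end orchestration: peaks -> enhancer filter -> classification ->
ChIP metaprofile -> differential expression -> linkage -> motif enrichment.

One structured config drives a run; every stage logs its parameters,
input hashes and output record counts into a machine-readable summary
(JSON, deterministically serialized), so re-running with the same config
and inputs reproduces the summary byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import de as de_mod
from . import linkage as linkage_mod
from . import motifs as motifs_mod
from . import peaks as peaks_mod
from . import tracks as tracks_mod
from .counts import CountMatrix
from .intervals import GenomicInterval, read_bed, read_tss_table, write_bed
from .simulate import GroundTruth, SimulationConfig, simulate_dataset

__all__ = ["RunConfig", "run_pipeline", "simulate_command", "score_command"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


_DEFAULT_STAGES = {
    "peaks": True,
    "classify": True,
    "chip": True,
    "de": True,
    "linkage": True,
    "motifs": True,
}

_DEFAULT_PARAMS: dict[str, Any] = {
    "peak": {"window_size": 177, "step": 88, "q_threshold": 0.001, "merge_gap": None},
    "mode": "presence",  # or "counts"
    "atac_contrast": ["vehicle", "T0"],
    "de_contrast": ["LPS", "T0+LPS"],
    "lps_contrast": ["vehicle", "LPS"],
    "q_cut": 0.05,
    "fc_cut": None,
    "link_window": 100_000,
    "n_null_draws": 1,
    "flank": 2000,
    "bin": 25,
    "chip_bin_size": 25,
    "motif_threshold_frac": 0.8,
}

_INPUT_KEYS = {
    "marked_enhancers",
    "fragments",
    "atac_conditions",
    "chip_track",
    "rna_counts",
    "rna_samples",
    "genes",
    "fasta",
    "pwms",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``inputs.fragments`` maps sample id -> fragment BED path and
    ``inputs.atac_conditions`` maps sample id -> condition label.
    Unknown keys anywhere are rejected.
    """

    inputs: dict[str, Any]
    output_dir: str
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: dict(_DEFAULT_STAGES))
    params: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULT_PARAMS))

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - _INPUT_KEYS
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        unknown = set(self.stages) - set(_DEFAULT_STAGES)
        if unknown:
            raise ValueError(f"unknown stage toggles: {sorted(unknown)}")
        unknown = set(self.params) - set(_DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        stages = dict(_DEFAULT_STAGES)
        stages.update(self.stages)
        self.stages = stages
        params = json.loads(json.dumps(_DEFAULT_PARAMS))
        for k, v in self.params.items():
            if isinstance(v, Mapping) and isinstance(params.get(k), dict):
                params[k].update(v)
            else:
                params[k] = v
        self.params = params

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        allowed = {"inputs", "output_dir", "seed", "stages", "params"}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "inputs": self.inputs,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "stages": self.stages,
            "params": self.params,
        }


def config_for_dataset(
    sim_dir: str | Path, output_dir: str | Path, seed: int = 0, **params: Any
) -> RunConfig:
    """RunConfig wired to the file layout written by
    :func:`cislink.simulate.simulate_dataset`."""
    sim_dir = Path(sim_dir)
    truth = GroundTruth.from_json(sim_dir / "ground_truth.json")
    cfg = truth.config
    fragments = {
        f"{cond}_rep{rep}": str(sim_dir / "fragments" / f"{cond}_rep{rep}.bed")
        for cond in cfg.conditions
        for rep in range(1, cfg.n_atac_reps + 1)
    }
    conditions = {s: s.rsplit("_rep", 1)[0] for s in fragments}
    return RunConfig(
        inputs={
            "marked_enhancers": str(sim_dir / "marked_enhancers.bed"),
            "fragments": fragments,
            "atac_conditions": conditions,
            "chip_track": str(sim_dir / "chip.bedgraph"),
            "rna_counts": str(sim_dir / "rna_counts.tsv"),
            "rna_samples": str(sim_dir / "rna_samples.tsv"),
            "genes": str(sim_dir / "genes.tsv"),
            "fasta": str(sim_dir / "genome.fa"),
            "pwms": None,
        },
        output_dir=str(output_dir),
        seed=seed,
        params=params,
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _genome_from_fasta(path: str | Path) -> dict[str, int]:
    genome: dict[str, int] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                name = line[1:].split()[0]
                genome[name] = 0
            elif name is not None:
                genome[name] += len(line.strip())
    return genome


def _score_bed(intervals: list[GenomicInterval], set_name: str) -> list[GenomicInterval]:
    out = []
    for iv in intervals:
        q = iv.score
        score = None
        if q is not None:
            score = 1000.0 if q <= 0 else min(1000.0, -10.0 * math.log10(q))
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end, set_name, score, "."))
    return out


def simulate_command(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate the synthetic dataset and its ground-truth manifest."""
    return simulate_dataset(config, outdir)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute enabled stages and write per-stage artifacts plus a
    ``summary.json`` run record.  A stage failure raises
    :class:`StageError` naming the stage; the partial summary on disk is
    marked incomplete."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    summary: dict[str, Any] = {
        "config": config.to_dict(),
        "input_hashes": {},
        "stages": {},
        "complete": False,
    }

    def save_summary() -> None:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def declare_input(key: str, path: str) -> str:
        summary["input_hashes"][f"{key}:{Path(path).name}"] = _sha256(path)
        return path

    try:
        genome = _genome_from_fasta(declare_input("fasta", config.inputs["fasta"]))
        marked = read_bed(declare_input("marked_enhancers", config.inputs["marked_enhancers"]))
        frag_paths = config.inputs["fragments"]
        conditions: dict[str, str] = config.inputs["atac_conditions"]
        fragments = {
            s: read_bed(declare_input("fragments", path))
            for s, path in sorted(frag_paths.items())
        }

        peaks_by_condition: dict[str, list[GenomicInterval]] = {}
        accessible_by_condition: dict[str, list[GenomicInterval]] = {}
        if config.stages["peaks"]:
            try:
                pk = p["peak"]
                params = peaks_mod.PeakCallParams(
                    window_size=pk["window_size"],
                    step=pk["step"],
                    q_threshold=pk["q_threshold"],
                    merge_gap=pk["merge_gap"],
                )
                stage: dict[str, Any] = {"params": pk, "n_peaks": {}, "capture_fraction": {}}
                for cond in sorted(set(conditions.values())):
                    pooled = [
                        f
                        for s, frs in fragments.items()
                        if conditions[s] == cond
                        for f in frs
                    ]
                    called = peaks_mod.call_peaks(pooled, genome, params)
                    filtered, capture = peaks_mod.filter_to_enhancers(called, marked)
                    peaks_by_condition[cond] = called
                    accessible_by_condition[cond] = filtered
                    stage["n_peaks"][cond] = len(called)
                    stage["capture_fraction"][cond] = None if math.isnan(capture) else capture
                    write_bed(_score_bed(called, f"peaks_{cond}"), outdir / f"peaks_{cond}.bed")
                summary["stages"]["peaks"] = stage
            except Exception as exc:  # noqa: BLE001
                raise StageError("peaks", str(exc)) from exc

        classification = None
        if config.stages["classify"]:
            try:
                cond_a, cond_b = p["atac_contrast"]
                if not peaks_by_condition and p["mode"] == "presence":
                    raise ValueError("presence mode requires the peaks stage")
                if p["mode"] == "presence":
                    classification = peaks_mod.classify_presence(
                        peaks_by_condition, marked, (cond_a, cond_b)
                    )
                elif p["mode"] == "counts":
                    cm = peaks_mod.count_fragments_per_enhancer(
                        marked, fragments, conditions
                    )
                    de_table, classification = peaks_mod.classify_counts(
                        cm, (cond_a, cond_b), marked, q_cut=p["q_cut"]
                    )
                    de_table.to_csv(outdir / "accessibility_de.tsv", sep="\t")
                else:
                    raise ValueError(f"unknown classification mode {p['mode']!r}")
                for set_name in ("closed", "opened", "stable"):
                    ivs = getattr(classification, set_name)
                    write_bed(
                        _score_bed(ivs, set_name), outdir / f"enhancers_{set_name}.bed"
                    )
                summary["stages"]["classify"] = {
                    "mode": p["mode"],
                    "contrast": [cond_a, cond_b],
                    "n_closed": len(classification.closed),
                    "n_opened": len(classification.opened),
                    "n_stable": len(classification.stable),
                }
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("classify", str(exc)) from exc

        if config.stages["chip"]:
            try:
                if classification is None:
                    raise ValueError("requires the classify stage (enhancer sets)")
                track = tracks_mod.read_bedgraph(
                    declare_input("chip_track", config.inputs["chip_track"]),
                    genome,
                    p["chip_bin_size"],
                )
                regions = classification.closed or classification.stable
                prof = tracks_mod.metaprofile(track, regions, p["flank"], p["bin"])
                pd.DataFrame({"offset": prof.offsets, "mean_signal": prof.values}).to_csv(
                    outdir / "chip_metaprofile.tsv", sep="\t", index=False
                )
                center = prof.values[len(prof.values) // 2 - 1 : len(prof.values) // 2 + 1].mean()
                flank_mean = (prof.values[:4].mean() + prof.values[-4:].mean()) / 2.0
                summary["stages"]["chip"] = {
                    "n_regions": prof.n_regions,
                    "n_dropped": prof.n_dropped,
                    "center_signal": float(center),
                    "flank_signal": float(flank_mean),
                }
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("chip", str(exc)) from exc

        gene_sets = None
        if config.stages["de"]:
            try:
                cm = CountMatrix.from_tsv(
                    declare_input("rna_counts", config.inputs["rna_counts"]),
                    declare_input("rna_samples", config.inputs["rna_samples"]),
                )
                results = de_mod.nb_wald_test(cm, tuple(p["de_contrast"]))
                lps_results = de_mod.nb_wald_test(cm, tuple(p["lps_contrast"]))
                gene_sets = de_mod.classify_genes(
                    results, q_cut=p["q_cut"], fc_cut=p["fc_cut"], lps_results=lps_results
                )
                gene_sets.table.to_csv(outdir / "de_results.tsv", sep="\t")
                n_rep = len(gene_sets.repressed)
                summary["stages"]["de"] = {
                    "contrast": p["de_contrast"],
                    "n_induced": len(gene_sets.induced),
                    "n_repressed": n_rep,
                    "n_lps_inducible": len(gene_sets.lps_inducible),
                    "frac_repressed_lps_inducible": (
                        len(gene_sets.repressed & gene_sets.lps_inducible) / n_rep
                        if n_rep
                        else None
                    ),
                }
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("de", str(exc)) from exc

        if config.stages["linkage"]:
            try:
                if gene_sets is None:
                    raise ValueError("requires the de stage (gene sets)")
                if classification is None:
                    raise ValueError("requires the classify stage (enhancer sets)")
                universe = read_tss_table(declare_input("genes", config.inputs["genes"]))
                by_id = {g.gene_id: g for g in universe}
                gsets = {
                    "induced": [by_id[g] for g in sorted(gene_sets.induced) if g in by_id],
                    "repressed": [by_id[g] for g in sorted(gene_sets.repressed) if g in by_id],
                }
                gsets = {k: v for k, v in gsets.items() if v}
                esets = {
                    "closed": classification.closed,
                    "opened": classification.opened,
                }
                analysis = linkage_mod.run_linkage_analysis(
                    gsets,
                    esets,
                    universe,
                    window=p["link_window"],
                    n_null_draws=p["n_null_draws"],
                    seed=config.seed,
                )
                analysis.table.to_csv(outdir / "linkage.tsv", sep="\t", index=False)
                analysis.posthoc.to_csv(outdir / "linkage_posthoc.tsv", sep="\t", index=False)
                summary["stages"]["linkage"] = {
                    "window": p["link_window"],
                    "fractions": {
                        f"{r.gene_set}|{r.enhancer_set}": r.linked_fraction
                        for r in analysis.table.itertuples()
                    },
                    "omnibus": {
                        r.enhancer_set: {"H": r.H, "p": r.p}
                        for r in analysis.omnibus.itertuples()
                    },
                }
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("linkage", str(exc)) from exc

        if config.stages["motifs"]:
            try:
                if classification is None:
                    raise ValueError("requires the classify stage (enhancer sets)")
                if config.inputs.get("pwms"):
                    pwms = motifs_mod.read_pwms(
                        declare_input("pwms", config.inputs["pwms"]),
                        threshold_frac=p["motif_threshold_frac"],
                    )
                else:
                    pwms = motifs_mod.load_builtin_pwms(p["motif_threshold_frac"])
                target = classification.closed or classification.stable
                table = motifs_mod.set_enrichment(
                    target, marked, config.inputs["fasta"], pwms
                )
                table.to_csv(outdir / "motif_enrichment.tsv", sep="\t")
                summary["stages"]["motifs"] = {
                    "target": "closed" if classification.closed else "stable",
                    "n_target": len(target),
                    "n_background": len(marked),
                    "results": {
                        m: {
                            "fold": None if math.isnan(r["fold_enrichment"]) else (
                                "inf" if math.isinf(r["fold_enrichment"]) else r["fold_enrichment"]
                            ),
                            "q": r["q"],
                        }
                        for m, r in table.iterrows()
                    },
                }
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise StageError("motifs", str(exc)) from exc

        summary["complete"] = True
        save_summary()
        return summary
    except StageError:
        save_summary()
        raise


# ---------------------------------------------------------------------------
# scoring against ground truth
# ---------------------------------------------------------------------------


def _sens_fdr(predicted: set, truth: set) -> dict[str, float | int]:
    tp = len(predicted & truth)
    sens = tp / len(truth) if truth else math.nan
    fdr = (len(predicted) - tp) / len(predicted) if predicted else math.nan
    return {
        "n_predicted": len(predicted),
        "n_true": len(truth),
        "sensitivity": None if math.isnan(sens) else sens,
        "fdr": None if math.isnan(fdr) else fdr,
    }


def score_command(output_dir: str | Path, truth: GroundTruth) -> dict[str, Any]:
    """Score a finished run's enhancer classification, DE calls and
    linkage fractions against the planted ground truth."""
    outdir = Path(output_dir)
    report: dict[str, Any] = {}

    closed_bed = outdir / "enhancers_closed.bed"
    if closed_bed.exists():
        predicted = {
            (iv.chrom, iv.start, iv.end) for iv in read_bed(closed_bed)
        }
        true_closed = {
            (r.chrom, int(r.start), int(r.end))
            for r in truth.enhancers[truth.enhancers["class"] == "T0_closed"].itertuples()
        }
        report["closed_enhancers"] = _sens_fdr(predicted, true_closed)

    de_tsv = outdir / "de_results.tsv"
    if de_tsv.exists():
        de_table = pd.read_csv(de_tsv, sep="\t", index_col=0)
        pred_rep = set(de_table.index[de_table["class"] == "repressed"])
        pred_ind = set(de_table.index[de_table["class"] == "induced"])
        report["repressed_genes"] = _sens_fdr(pred_rep, set(truth.gene_ids("repressed")))
        report["induced_genes"] = _sens_fdr(pred_ind, set(truth.gene_ids("induced")))

    link_tsv = outdir / "linkage.tsv"
    if link_tsv.exists():
        link = pd.read_csv(link_tsv, sep="\t")
        cfg = truth.config
        deltas = {}
        for r in link.itertuples():
            planted = None
            if r.gene_set == "repressed" and r.enhancer_set == "closed":
                planted = cfg.link_prob_target
            elif r.gene_set.startswith("random") and r.enhancer_set == "closed":
                planted = cfg.link_prob_background
            if planted is not None:
                deltas[f"{r.gene_set}|{r.enhancer_set}"] = {
                    "observed": r.linked_fraction,
                    "planted": planted,
                    "delta": r.linked_fraction - planted,
                }
        report["linkage"] = deltas

    with open(outdir / "score.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
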
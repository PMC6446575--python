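"""Seeded multi-omic toy-data generator with planted ground truth.

Emulates a four-condition macrophage stimulation design — vehicle, LXR
agonist (T0), LPS, and T0+LPS — with four ATAC replicates and three RNA
replicates per condition.  The generator plants:

* enhancer *closure* (and some opening) under T0: per-enhancer fragment
  counts drop (rise) by a configured log2 effect in T0-containing
  conditions;
* ChIP enrichment bumps coincident with the closed enhancers;
* differentially expressed genes whose TSSs are preferentially placed
  within a linkage window (100 kb) of the affected enhancers;
* a DR4-geometry motif (AGGTCAnnnnAGGTCA) in a configured fraction of
  closed-enhancer sequences versus background.

Everything is driven by one seed; per-stream generators are derived from
it with fixed offsets, so each stage is independently reproducible and
the emitted files are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .intervals import (
    GeneModel,
    GenomicInterval,
    _ChromIndex,
    write_bed,
    write_tss_table,
)
from .tracks import SignalTrack, write_bedgraph

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_annotation",
    "simulate_atac_fragments",
    "simulate_chip_track",
    "simulate_rna_counts",
    "simulate_dataset",
    "simulate_count_matrix",
    "place_gene_tss",
    "DR4_CONSENSUS",
]

DR4_CONSENSUS = "AGGTCAnnnnAGGTCA"

# fixed per-stream offsets for deriving independent generators from one seed
_STREAM = {"annotation": 1, "atac": 2, "chip": 3, "rna": 4, "linkage": 5}

CONDITIONS = ("vehicle", "T0", "LPS", "T0+LPS")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults chosen to mirror
    the emulated design (4 conditions, 4 ATAC / 3 RNA replicates).

    Accessibility effects are signed log2 fold changes applied in
    T0-containing conditions: planted-closed enhancers get ``lfc_access``
    (negative by default), planted-opened enhancers its negation.
    """

    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 10_000_000),
        ("chr2", 10_000_000),
        ("chr3", 10_000_000),
        ("chr4", 10_000_000),
    )
    n_genes: int = 1000
    n_enhancers: int = 300
    conditions: tuple[str, ...] = CONDITIONS
    n_atac_reps: int = 4
    n_rna_reps: int = 3
    frac_closed: float = 0.2
    frac_opened: float = 0.1
    lfc_access: float = -1.5
    lfc_expr: float = 1.5
    nb_dispersion: float = 0.05
    mean_fragments_per_enhancer: float = 100.0
    background_fragment_rate: float = 5e-5  # fragments per bp per sample
    chip_enrichment_fold: float = 8.0
    chip_background_rate: float = 0.02  # non-closed enhancers that are ChIP+
    chip_bump_halfwidth: int = 500  # bp; triangular bump half-width
    chip_bin_size: int = 25
    link_prob_target: float = 0.8
    link_prob_background: float = 0.2
    link_window: int = 100_000
    motif_plant_rate_target: float = 0.3
    motif_plant_rate_background: float = 0.02
    frac_repressed: float = 0.15
    frac_induced: float = 0.15
    lps_inducible_frac: float = 0.6
    rna_mean: float = 200.0
    enhancer_length: int = 500
    fragment_length: int = 100
    decoy_frac: float = 0.3  # share of accessible regions NOT histone-marked
    marked_extra_frac: float = 0.2  # marked regions with no accessibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_closed", "frac_opened", "link_prob_target", "link_prob_background",
            "motif_plant_rate_target", "motif_plant_rate_background",
            "frac_repressed", "frac_induced", "lps_inducible_frac",
            "chip_background_rate", "decoy_frac", "marked_extra_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_closed + self.frac_opened > 1.0:
            raise ValueError("frac_closed + frac_opened must be <= 1")
        if self.frac_repressed + self.frac_induced > 1.0:
            raise ValueError("frac_repressed + frac_induced must be <= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.fragment_length >= self.enhancer_length:
            raise ValueError("fragment_length must be < enhancer_length")
        self.genome = tuple((str(c), int(L)) for c, L in self.genome)
        self.conditions = tuple(self.conditions)

    @property
    def genome_dict(self) -> dict[str, int]:
        return dict(self.genome)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAM[stream], self.seed])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "genome" in d:
            d["genome"] = tuple((c, int(L)) for c, L in d["genome"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage.

    ``enhancers``: id, coords, class (T0_closed / T0_opened / stable /
    decoy), ChIP-positive flag, motif-planted flag.
    ``genes``: id, TSS, class (repressed / induced / null), true log2
    effects, LPS-inducibility, id of the enhancer a linked gene was
    placed next to (empty if placed away from affected enhancers).
    """

    enhancers: pd.DataFrame
    genes: pd.DataFrame
    config: SimulationConfig

    def enhancer_set(self, cls: str) -> list[GenomicInterval]:
        rows = self.enhancers[self.enhancers["class"] == cls]
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=r.id)
            for r in rows.itertuples()
        ]

    def gene_ids(self, cls: str) -> list[str]:
        return list(self.genes.loc[self.genes["class"] == cls, "gene_id"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "enhancers": self.enhancers.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        enh_cols = ["id", "chrom", "start", "end", "class", "chip_positive", "motif_planted"]
        gene_cols = ["gene_id", "chrom", "strand", "tss", "class", "true_lfc_t0",
                     "lps_inducible", "linked_enhancer"]
        return cls(
            pd.DataFrame(payload["enhancers"])[enh_cols],
            pd.DataFrame(payload["genes"])[gene_cols],
            SimulationConfig.from_dict(payload["config"]),
        )


@dataclass
class Annotation:
    """In-memory annotation bundle emitted by :func:`generate_annotation`."""

    sequences: dict[str, np.ndarray]  # uint8 ASCII codes per chromosome
    genes: list[GeneModel]
    enhancers: list[GenomicInterval]  # true enhancers (marked, accessible)
    decoys: list[GenomicInterval]  # accessible but unmarked
    marked: list[GenomicInterval]  # histone-marked superset

    @property
    def accessible(self) -> list[GenomicInterval]:
        return sorted(self.enhancers + self.decoys)

    def fasta_text(self, width: int = 60) -> str:
        chunks = []
        for chrom, arr in self.sequences.items():
            chunks.append(f">{chrom}\n")
            s = arr.tobytes().decode("ascii")
            chunks.extend(s[i : i + width] + "\n" for i in range(0, len(s), width))
        return "".join(chunks)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------


def _place_nonoverlapping(
    rng: np.random.Generator,
    genome: Sequence[tuple[str, int]],
    n: int,
    length: int,
    occupied: dict[str, list[tuple[int, int]]],
    max_tries_per_interval: int = 1000,
) -> list[tuple[str, int]]:
    """Place n intervals of fixed length uniformly, rejecting overlaps."""
    chroms = [c for c, _ in genome]
    lens = np.array([L for _, L in genome], dtype=float)
    probs = lens / lens.sum()
    placed: list[tuple[str, int]] = []
    for _ in range(n):
        for _try in range(max_tries_per_interval):
            ci = rng.choice(len(chroms), p=probs)
            chrom, L = genome[ci]
            if L <= length:
                continue
            start = int(rng.integers(0, L - length))
            ok = all(
                start + length <= s or e <= start for s, e in occupied.get(chrom, [])
            )
            if ok:
                occupied.setdefault(chrom, []).append((start, start + length))
                placed.append((chrom, start))
                break
        else:
            raise ValueError(
                "could not place non-overlapping intervals; use a larger genome"
            )
    return placed


def place_gene_tss(
    rng: np.random.Generator,
    genome: Sequence[tuple[str, int]],
    target_set: Sequence[GenomicInterval],
    avoid_sets: Sequence[GenomicInterval],
    link_prob: float,
    window: int,
    max_tries: int = 10_000,
) -> tuple[str, int, str]:
    """Place one TSS near ``target_set`` with probability ``link_prob``.

    A "near" placement is uniform within ``window`` bp of a uniformly
    chosen target enhancer's edges; a "far" placement is uniform over the
    genome, rejected until it is more than ``window`` bp from every
    interval in ``avoid_sets``.  Returns (chrom, tss, linked_enhancer_id).
    """
    genome = list(genome)
    glen = {c: L for c, L in genome}
    index = _ChromIndex(list(avoid_sets)) if avoid_sets else None
    if target_set and rng.random() < link_prob:
        e = target_set[int(rng.integers(0, len(target_set)))]
        lo = max(0, e.start - window)
        hi = min(glen[e.chrom] - 1, e.end - 1 + window)
        pos = int(rng.integers(lo, hi + 1))
        return e.chrom, pos, (e.name or f"{e.chrom}:{e.start}-{e.end}")
    lens = np.array([L for _, L in genome], dtype=float)
    probs = lens / lens.sum()
    for _ in range(max_tries):
        ci = rng.choice(len(genome), p=probs)
        chrom, L = genome[ci]
        pos = int(rng.integers(0, L))
        if index is None:
            return chrom, pos, ""
        _, d = index.nearest(chrom, pos)
        if d > window:
            return chrom, pos, ""
    raise ValueError("could not place an unlinked TSS; use a larger genome")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_annotation(config: SimulationConfig) -> tuple[Annotation, GroundTruth]:
    """Generate genome sequence, enhancers, decoys, marked set, genes and
    the ground-truth tables (gene expression effects included)."""
    rng = config.rng("annotation")
    glen = config.genome_dict

    # accessible regions: true enhancers + unmarked decoys
    n_enh = config.n_enhancers
    n_decoy = (
        0
        if config.decoy_frac == 0
        else int(round(n_enh * config.decoy_frac / (1.0 - config.decoy_frac)))
    )
    n_marked_extra = int(round(n_enh * config.marked_extra_frac))
    occupied: dict[str, list[tuple[int, int]]] = {}
    pos_enh = _place_nonoverlapping(rng, config.genome, n_enh, config.enhancer_length, occupied)
    pos_dec = _place_nonoverlapping(rng, config.genome, n_decoy, config.enhancer_length, occupied)
    pos_ext = _place_nonoverlapping(rng, config.genome, n_marked_extra, config.enhancer_length, occupied)

    L = config.enhancer_length
    enhancers = [
        GenomicInterval(c, s, s + L, name=f"enh_{i:04d}") for i, (c, s) in enumerate(pos_enh)
    ]
    decoys = [
        GenomicInterval(c, s, s + L, name=f"decoy_{i:04d}") for i, (c, s) in enumerate(pos_dec)
    ]
    extra_marked = [
        GenomicInterval(c, s, s + L, name=f"mark_{i:04d}") for i, (c, s) in enumerate(pos_ext)
    ]
    marked = sorted(enhancers + extra_marked)

    # enhancer classes
    n_closed = int(round(config.frac_closed * n_enh))
    n_opened = int(round(config.frac_opened * n_enh))
    perm = rng.permutation(n_enh)
    classes = np.array(["stable"] * n_enh, dtype=object)
    classes[perm[:n_closed]] = "T0_closed"
    classes[perm[n_closed : n_closed + n_opened]] = "T0_opened"

    chip_pos = classes == "T0_closed"
    bg_draw = rng.random(n_enh) < config.chip_background_rate
    chip_pos = chip_pos | (bg_draw & (classes != "T0_closed"))

    motif_draw = rng.random(n_enh)
    motif = np.where(
        classes == "T0_closed",
        motif_draw < config.motif_plant_rate_target,
        motif_draw < config.motif_plant_rate_background,
    )

    enh_df = pd.DataFrame(
        {
            "id": [e.name for e in enhancers] + [d.name for d in decoys],
            "chrom": [e.chrom for e in enhancers] + [d.chrom for d in decoys],
            "start": [e.start for e in enhancers] + [d.start for d in decoys],
            "end": [e.end for e in enhancers] + [d.end for d in decoys],
            "class": list(classes) + ["decoy"] * n_decoy,
            "chip_positive": list(chip_pos) + [False] * n_decoy,
            "motif_planted": list(motif) + [False] * n_decoy,
        }
    )

    # genes: DE classes, effects, and linkage-aware TSS placement
    n_rep = int(round(config.frac_repressed * config.n_genes))
    n_ind = int(round(config.frac_induced * config.n_genes))
    gene_classes = (
        ["repressed"] * n_rep
        + ["induced"] * n_ind
        + ["null"] * (config.n_genes - n_rep - n_ind)
    )
    closed_set = [e for e, c in zip(enhancers, classes) if c == "T0_closed"]
    opened_set = [e for e, c in zip(enhancers, classes) if c == "T0_opened"]
    affected = closed_set + opened_set

    rows = []
    for i, gcls in enumerate(gene_classes):
        if gcls == "repressed":
            target, prob = closed_set, config.link_prob_target
            lfc_t0 = -config.lfc_expr
        elif gcls == "induced":
            target, prob = opened_set, config.link_prob_target
            lfc_t0 = config.lfc_expr
        else:
            target, prob = closed_set, config.link_prob_background
            lfc_t0 = 0.0
        chrom, tss, linked = place_gene_tss(
            rng, config.genome, target, affected, prob, config.link_window
        )
        lps_ind = bool(gcls == "repressed" and rng.random() < config.lps_inducible_frac)
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "gene_id": f"gene_{i:04d}",
                "chrom": chrom,
                "strand": strand,
                "tss": tss,
                "class": gcls,
                "true_lfc_t0": lfc_t0,
                "lps_inducible": lps_ind,
                "linked_enhancer": linked,
            }
        )
    gene_df = pd.DataFrame(rows)
    genes = [
        GeneModel(r.gene_id, r.chrom, r.strand, int(r.tss)) for r in gene_df.itertuples()
    ]

    # genome sequence with planted DR4 motifs in motif-positive enhancers
    sequences = {
        c: _BASES[rng.integers(0, 4, size=Lc, dtype=np.int64)] for c, Lc in glen.items()
    }
    core = np.frombuffer(b"AGGTCA", dtype=np.uint8)
    for e, has_motif in zip(enhancers, motif):
        if not has_motif:
            continue
        mlen = len(DR4_CONSENSUS)
        off = int(rng.integers(0, e.length - mlen + 1))
        s = e.start + off
        seq = sequences[e.chrom]
        seq[s : s + 6] = core
        seq[s + 10 : s + 16] = core  # middle 4 bases stay background

    truth = GroundTruth(enh_df, gene_df, config)
    return Annotation(sequences, genes, enhancers, decoys, marked), truth


# ---------------------------------------------------------------------------
# NB sampling
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion*mu^2."""
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def _condition_multiplier(condition: str, lfc_t0: float, lfc_lps: float) -> float:
    x = 0.0
    if "T0" in condition:
        x += lfc_t0
    if "LPS" in condition:
        x += lfc_lps
    return 2.0**x


# ---------------------------------------------------------------------------
# ATAC fragments
# ---------------------------------------------------------------------------


def simulate_atac_fragments(
    config: SimulationConfig, annotation: Annotation, truth: GroundTruth
) -> dict[str, list[GenomicInterval]]:
    """Per-sample fragment interval sets.

    Per accessible region and sample, fragment counts are NB with mean
    ``mean_fragments_per_enhancer`` scaled by the planted condition
    effect; fragments are placed uniformly inside the region.  Background
    fragments land uniformly genome-wide at ``background_fragment_rate``
    per bp per sample.  Sample ids are ``{condition}_rep{k}``.
    """
    rng = config.rng("atac")
    glen = config.genome_dict
    total_len = sum(glen.values())
    flen = config.fragment_length

    regions = annotation.enhancers + annotation.decoys
    cls_by_id = dict(zip(truth.enhancers["id"], truth.enhancers["class"]))

    out: dict[str, list[GenomicInterval]] = {}
    for condition in config.conditions:
        for rep in range(1, config.n_atac_reps + 1):
            sample = f"{condition}_rep{rep}"
            frags: list[GenomicInterval] = []
            for region in regions:
                cls = cls_by_id[region.name]
                lfc = 0.0
                if cls == "T0_closed":
                    lfc = config.lfc_access
                elif cls == "T0_opened":
                    lfc = -config.lfc_access
                mu = config.mean_fragments_per_enhancer * _condition_multiplier(
                    condition, lfc, 0.0
                )
                n = int(_nb_draw(rng, np.array([mu]), config.nb_dispersion)[0])
                if n > 0:
                    starts = rng.integers(region.start, region.end - flen + 1, size=n)
                    frags.extend(
                        GenomicInterval(region.chrom, int(s), int(s) + flen)
                        for s in np.sort(starts)
                    )
            n_bg = rng.poisson(config.background_fragment_rate * total_len)
            if n_bg > 0:
                chroms = list(glen)
                lens = np.array([glen[c] for c in chroms], dtype=float)
                ci = rng.choice(len(chroms), size=n_bg, p=lens / lens.sum())
                for c_i in ci:
                    chrom = chroms[c_i]
                    s = int(rng.integers(0, glen[chrom] - flen + 1))
                    frags.append(GenomicInterval(chrom, s, s + flen))
            frags.sort()
            out[sample] = frags
    return out


def atac_sample_conditions(config: SimulationConfig) -> dict[str, str]:
    return {
        f"{cond}_rep{rep}": cond
        for cond in config.conditions
        for rep in range(1, config.n_atac_reps + 1)
    }


# ---------------------------------------------------------------------------
# ChIP track
# ---------------------------------------------------------------------------


def simulate_chip_track(config: SimulationConfig, truth: GroundTruth) -> SignalTrack:
    """Deterministic ChIP signal: baseline 1.0 plus a symmetric triangular
    bump of height (fold - 1) at every ChIP-positive enhancer center."""
    glen = config.genome_dict
    bs = config.chip_bin_size
    values = {
        c: np.ones(-(-L // bs), dtype=np.float64) for c, L in glen.items()
    }
    height = config.chip_enrichment_fold - 1.0
    w = config.chip_bump_halfwidth
    pos = truth.enhancers[truth.enhancers["chip_positive"]]
    for r in pos.itertuples():
        center = (int(r.start) + int(r.end)) // 2
        arr = values[r.chrom]
        b0 = max(0, (center - w) // bs)
        b1 = min(len(arr) - 1, (center + w) // bs)
        bins = np.arange(b0, b1 + 1)
        bin_centers = bins * bs + bs / 2.0
        bump = height * np.maximum(0.0, 1.0 - np.abs(bin_centers - center) / w)
        arr[bins] += bump
    return SignalTrack(bs, glen, values, normalization="RPGC")


def expected_chip_mean(config: SimulationConfig, truth: GroundTruth) -> float:
    """Closed-form genome mean of the simulated ChIP track: baseline 1
    plus total triangular bump mass over genome length."""
    n_pos = int(truth.enhancers["chip_positive"].sum())
    mass = n_pos * (config.chip_enrichment_fold - 1.0) * config.chip_bump_halfwidth
    return 1.0 + mass / sum(config.genome_dict.values())


# ---------------------------------------------------------------------------
# RNA counts
# ---------------------------------------------------------------------------


def simulate_rna_counts(config: SimulationConfig, truth: GroundTruth) -> CountMatrix:
    """NB gene expression counts for every condition x replicate.

    Planted T0 effects apply in T0-containing conditions; LPS-inducible
    genes additionally gain ``lfc_expr`` in LPS-containing conditions.
    """
    rng = config.rng("rna")
    genes = truth.genes
    lfc_t0 = genes["true_lfc_t0"].to_numpy(dtype=float)
    lfc_lps = np.where(genes["lps_inducible"].to_numpy(dtype=bool), config.lfc_expr, 0.0)

    samples, conds = [], {}
    data = {}
    for condition in config.conditions:
        for rep in range(1, config.n_rna_reps + 1):
            sample = f"{condition}_rep{rep}"
            mult = np.array(
                [
                    _condition_multiplier(condition, t, l)
                    for t, l in zip(lfc_t0, lfc_lps)
                ]
            )
            data[sample] = _nb_draw(rng, config.rna_mean * mult, config.nb_dispersion)
            samples.append(sample)
            conds[sample] = condition
    counts = pd.DataFrame(data, index=pd.Index(genes["gene_id"], name="feature_id"))
    return CountMatrix(counts, pd.Series(conds))


def rna_sample_conditions(config: SimulationConfig) -> dict[str, str]:
    return {
        f"{cond}_rep{rep}": cond
        for cond in config.conditions
        for rep in range(1, config.n_rna_reps + 1)
    }


# ---------------------------------------------------------------------------
# calibration-style direct count simulation
# ---------------------------------------------------------------------------


def simulate_count_matrix(
    n_features: int,
    n_affected: int,
    lfc: float,
    mean: float,
    dispersion: float,
    n_reps: int,
    conditions: tuple[str, str] = ("A", "B"),
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """Two-condition NB count matrix with the first ``n_affected``
    features carrying ``lfc`` (log2, condition B vs A).

    Returns the matrix and the boolean affected mask — the workhorse for
    power/FDR calibration of the count-mode tests.
    """
    rng = np.random.default_rng([17, seed])
    affected = np.zeros(n_features, dtype=bool)
    affected[:n_affected] = True
    mu_a = np.full(n_features, mean)
    mu_b = np.where(affected, mean * 2.0**lfc, mean)
    data = {}
    conds = {}
    for cond, mu in zip(conditions, (mu_a, mu_b)):
        for rep in range(1, n_reps + 1):
            sample = f"{cond}_rep{rep}"
            data[sample] = _nb_draw(rng, mu, dispersion)
            conds[sample] = cond
    ids = pd.Index([f"f_{i:05d}" for i in range(n_features)], name="feature_id")
    cm = CountMatrix(pd.DataFrame(data, index=ids), pd.Series(conds))
    return cm, affected


# ---------------------------------------------------------------------------
# full dataset emission
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Generate and write the complete synthetic dataset.

    Emits: genome.fa, genes.tsv, enhancers.bed, marked_enhancers.bed,
    fragments/<sample>.bed, chip.bedgraph, rna_counts.tsv,
    rna_samples.tsv, and ground_truth.json under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth = generate_annotation(config)

    (outdir / "genome.fa").write_text(annotation.fasta_text())
    write_tss_table(annotation.genes, outdir / "genes.tsv")
    write_bed(annotation.accessible, outdir / "enhancers.bed")
    write_bed(annotation.marked, outdir / "marked_enhancers.bed")

    fragdir = outdir / "fragments"
    fragdir.mkdir(exist_ok=True)
    fragments = simulate_atac_fragments(config, annotation, truth)
    for sample in sorted(fragments):
        write_bed(fragments[sample], fragdir / f"{sample}.bed")

    write_bedgraph(simulate_chip_track(config, truth), outdir / "chip.bedgraph")

    rna = simulate_rna_counts(config, truth)
    rna.to_tsv(outdir / "rna_counts.tsv", outdir / "rna_samples.tsv")

    truth.to_json(outdir / "ground_truth.json")
    return truth
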
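"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here at desk scale:

- a structured diploid genotype panel under the Balding–Nichols model
  (population allele frequencies Beta-distributed around an ancestral
  frequency with differentiation parameter F), with per-subgenome diversity
  scaling by polymorphic-site thinning, missingness, and read depths;
- homoeolog-triplet expression counts with a planted fraction of biased
  triplets at a configured log2 effect size, under a negative-binomial
  noise model;
- genome FASTA with telomeric repeats and N-gap runs planted per an
  explicit per-chromosome plan.

Each generator is deterministic given its config (seed included) and
returns a truth record sufficient to compute every expected statistic
without re-reading the generated files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dominance import ExpressionTable, SyntelogTripletSet
from .popgen import (
    MISSING,
    SUBGENOME_LABELS,
    GenotypeMatrix,
    SubgenomeMap,
    ValidationError,
    write_vcf,
)

logger = logging.getLogger("subgenomics")

#: chromosome → subgenome assignment of the hexaploid camelina reference
CAMELINA_CHROMOSOME_SUBGENOMES: dict[str, str] = {
    **{f"chr{i}": "SG1" for i in (4, 7, 8, 11, 14, 19)},
    **{f"chr{i}": "SG2" for i in (1, 3, 6, 10, 13, 16, 18)},
    **{f"chr{i}": "SG3" for i in (2, 5, 9, 12, 15, 17, 20)},
}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_chrom_layout() -> tuple[tuple[str, str, int], ...]:
    # two chromosomes per subgenome at 1 Mb: small enough for tests, large
    # enough that windows and positions behave like real coordinates
    return tuple(
        (f"chr{i+1}", sg, 1_000_000)
        for i, sg in enumerate(["SG1", "SG1", "SG2", "SG2", "SG3", "SG3"])
    )


@dataclass
class GenotypeSimConfig:
    """Structured-panel genotype simulation parameters.

    Defaults mirror the diversity-panel design under study: 222 diploid
    accessions in K = 4 subpopulations at low-to-moderate differentiation,
    with SG2 slightly more and SG3 markedly less diverse than SG1 (scale
    factors 1.00 / 1.22 / 0.79, the observed subgenome π ratios).
    """

    n_pops: int = 4
    pop_sizes: tuple[int, ...] = (56, 56, 55, 55)
    fst: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)
    n_sites: int = 5000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.02
    diversity_scale: dict[str, float] = field(
        default_factory=lambda: {"SG1": 1.00, "SG2": 1.22, "SG3": 0.79}
    )
    chromosomes: tuple[tuple[str, str, int], ...] = field(
        default_factory=_default_chrom_layout
    )
    mean_depth: float | None = 35.0

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != self.n_pops or len(self.fst) != self.n_pops:
            raise ValidationError("pop_sizes and fst must have n_pops entries")
        if any(s < 1 for s in self.pop_sizes):
            raise ValidationError("population sizes must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if any(not 0 <= f <= 1 for f in self.fst):
            raise ValidationError("F values must be in [0, 1]")
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")


def _default_bias_plan() -> dict[str, tuple[str, float, float] | None]:
    # planted SG3 bias in the reproductive organs, null elsewhere —
    # the qualitative pattern the dominance workflow is meant to detect
    return {
        "leaf": None,
        "mj_leaf": None,
        "root": None,
        "flower": ("SG3", 0.10, 3.0),
        "flower_bud": ("SG3", 0.10, 3.0),
        "young_fruit": ("SG3", 0.10, 3.0),
    }


@dataclass
class ExpressionSimConfig:
    """Homoeolog-triplet expression simulation parameters.

    ``bias_plan`` maps organ → (target subgenome, biased fraction, log2
    effect) or None for a null organ.  Counts follow a negative binomial
    with gene-wise constant dispersion (var = μ + φμ²).
    """

    n_triplets: int = 2000
    organs: tuple[str, ...] = (
        "leaf", "mj_leaf", "root", "flower", "flower_bud", "young_fruit",
    )
    bias_plan: dict[str, tuple[str, float, float] | None] = field(
        default_factory=_default_bias_plan
    )
    dispersion: float = 0.1
    baseline_log_mean: float = 3.5  # natural-log mean of expression level
    baseline_log_sd: float = 1.0
    library_size: float = 5e6
    length_range: tuple[int, int] = (500, 5000)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.n_triplets < 1:
            raise ValidationError("n_triplets must be >= 1")
        for organ, plan in self.bias_plan.items():
            if plan is None:
                continue
            sg, frac, eff = plan
            if sg not in SUBGENOME_LABELS:
                raise ValidationError(f"unknown subgenome {sg!r} in bias plan")
            if not 0 <= frac <= 1:
                raise ValidationError("bias fraction must be in [0, 1]")
            if not np.isfinite(eff):
                raise ValidationError("log2 effect must be finite")


@dataclass
class ChromosomePlan:
    """Per-chromosome plant plan for the genome generator."""

    name: str
    subgenome: str
    length: int
    telomere_start_copies: int = 0  # tandem motif copies planted at the start
    telomere_end_copies: int = 0
    gaps: tuple[tuple[int, int], ...] = ()  # (1-based start, length) N-runs


def _default_genome_plan() -> tuple[ChromosomePlan, ...]:
    # 20 chromosomes with the camelina chromosome→subgenome layout and the
    # assembly's telomere tally: 7 both ends, 10 one end, 3 neither
    plans = []
    end_states = (
        [(12, 12)] * 7 + [(12, 0)] * 5 + [(0, 12)] * 5 + [(0, 0)] * 3
    )
    for i, (s, e) in enumerate(end_states, start=1):
        name = f"chr{i}"
        plans.append(
            ChromosomePlan(
                name=name,
                subgenome=CAMELINA_CHROMOSOME_SUBGENOMES[name],
                length=30_000,
                telomere_start_copies=s,
                telomere_end_copies=e,
                gaps=((15_000, 100),) if i % 4 == 0 else (),
            )
        )
    return tuple(plans)


@dataclass
class GenomeSimConfig:
    chromosomes: tuple[ChromosomePlan, ...] = field(default_factory=_default_genome_plan)
    telomere_motif: str = "TTTAGGG"


@dataclass
class SimConfig:
    """Full parameterization of the three generators plus the global seed."""

    seed: int = 1
    genotypes: GenotypeSimConfig = field(default_factory=GenotypeSimConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    genome: GenomeSimConfig = field(default_factory=GenomeSimConfig)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = json.load(fh)
        geno = raw.get("genotypes", {})
        if "chromosomes" in geno:
            geno["chromosomes"] = tuple(tuple(c) for c in geno["chromosomes"])
        for key in ("pop_sizes", "fst", "ancestral_freq_range"):
            if key in geno:
                geno[key] = tuple(geno[key])
        expr = raw.get("expression", {})
        if "organs" in expr:
            expr["organs"] = tuple(expr["organs"])
        if "length_range" in expr:
            expr["length_range"] = tuple(expr["length_range"])
        if "bias_plan" in expr:
            expr["bias_plan"] = {
                k: (tuple(v) if v is not None else None)
                for k, v in expr["bias_plan"].items()
            }
        genome = raw.get("genome", {})
        if "chromosomes" in genome:
            genome["chromosomes"] = tuple(
                ChromosomePlan(
                    **{**c, "gaps": tuple(tuple(g) for g in c.get("gaps", []))}
                )
                for c in genome["chromosomes"]
            )
        return cls(
            seed=raw.get("seed", 1),
            genotypes=GenotypeSimConfig(**geno),
            expression=ExpressionSimConfig(**expr),
            genome=GenomeSimConfig(**genome),
        )


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------


def simulate_structured_genotypes(
    cfg: GenotypeSimConfig,
    seed: int = 1,
    out_dir: str | Path | None = None,
) -> tuple[GenotypeMatrix, dict[str, str], SubgenomeMap, dict]:
    """Balding–Nichols structured genotype panel.

    Per site, an ancestral frequency ``p`` is drawn uniformly from the
    configured range; each population's frequency is Beta(p(1−F)/F,
    (1−p)(1−F)/F) (point mass at p when F → 0, Bernoulli(p) when F → 1);
    diploid genotypes are Binomial(2, freq).  Per-subgenome diversity
    scaling thins polymorphic sites with probability scale/max(scale).
    Missing calls are planted uniformly at random.

    Returns ``(genotype matrix, sample→population map, subgenome map,
    truth record)``; with ``out_dir`` also writes ``genotypes.vcf``,
    ``popmap.tsv``, ``sgmap.tsv`` and ``truth.json``.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [c for c, _, _ in cfg.chromosomes]
    chrom_sg = {c: sg for c, sg, _ in cfg.chromosomes}
    chrom_len = {c: int(ln) for c, _, ln in cfg.chromosomes}
    sgmap = SubgenomeMap(assignment=chrom_sg, lengths=chrom_len)

    total_bp = sum(chrom_len.values())
    # allocate sites to chromosomes proportional to length (largest remainder)
    alloc = {c: int(cfg.n_sites * chrom_len[c] / total_bp) for c in chrom_names}
    remainder = cfg.n_sites - sum(alloc.values())
    for c in chrom_names[:remainder]:
        alloc[c] += 1

    max_scale = max(cfg.diversity_scale.get(sg, 1.0) for sg in set(chrom_sg.values()))
    site_chrom: list[str] = []
    site_pos: list[int] = []
    for c in chrom_names:
        k = alloc[c]
        if k == 0:
            continue
        pos = np.sort(rng.choice(chrom_len[c], size=min(k, chrom_len[c]), replace=False)) + 1
        survive = rng.random(pos.size) < (
            cfg.diversity_scale.get(chrom_sg[c], 1.0) / max_scale
        )
        pos = pos[survive]
        site_chrom.extend([c] * pos.size)
        site_pos.extend(int(p) for p in pos)
    n_sites = len(site_pos)

    samples: list[str] = []
    popmap: dict[str, str] = {}
    for k, size in enumerate(cfg.pop_sizes):
        for i in range(size):
            name = f"pop{k+1}_s{i+1:03d}"
            samples.append(name)
            popmap[name] = f"pop{k+1}"
    n_samples = len(samples)

    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=n_sites)
    pop_freq = np.empty((n_sites, cfg.n_pops))
    for k, f in enumerate(cfg.fst):
        if f <= 0:
            pop_freq[:, k] = p_anc
        elif f >= 1:
            pop_freq[:, k] = (rng.random(n_sites) < p_anc).astype(float)
        else:
            shape = (1.0 - f) / f
            pop_freq[:, k] = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)

    calls = np.empty((n_sites, n_samples), dtype=np.int8)
    col = 0
    for k, size in enumerate(cfg.pop_sizes):
        calls[:, col : col + size] = rng.binomial(
            2, pop_freq[:, k][:, None], size=(n_sites, size)
        ).astype(np.int8)
        col += size
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING
    depths = None
    if cfg.mean_depth is not None:
        depths = rng.poisson(cfg.mean_depth, size=calls.shape).astype(np.int64)

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame(
        {"chrom": site_chrom, "pos": np.array(site_pos, dtype=np.int64),
         "ref": bases[ref_idx], "alts": [(a,) for a in bases[alt_idx]]}
    )
    gm = GenotypeMatrix(sites=sites, samples=samples, calls=calls, depths=depths)

    # expected pairwise-difference probability per site for the pooled panel:
    # two haplotypes drawn from pops k, l with weights w_k w_l differ with
    # probability q_k(1−q_l) + q_l(1−q_k); summing gives 2·q̄(1−q̄)
    w = np.array(cfg.pop_sizes, dtype=float) / sum(cfg.pop_sizes)
    q_bar = pop_freq @ w
    exp_diff = 2 * q_bar * (1 - q_bar)

    sg_of_site = np.array([chrom_sg[c] for c in site_chrom])
    expected_pi = {}
    for sg in sgmap.labels:
        bp = sum(ln for c, s, ln in cfg.chromosomes if s == sg)
        sel = sg_of_site == sg
        expected_pi[sg] = float(exp_diff[sel].sum() / bp) if bp else float("nan")

    truth = {
        "seed": seed,
        "fst": list(cfg.fst),
        "pop_sizes": list(cfg.pop_sizes),
        "ancestral_freq": p_anc.tolist(),
        "pop_freq": pop_freq.tolist(),
        "site_chrom": site_chrom,
        "site_pos": site_pos,
        "expected_pi_per_bp": expected_pi,
        "n_sites": n_sites,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(gm, out / "genotypes.vcf", contig_lengths=chrom_len)
        pd.DataFrame({"sample": samples, "pop": [popmap[s] for s in samples]}).to_csv(
            out / "popmap.tsv", sep="\t", index=False
        )
        sgmap.to_tsv(out / "sgmap.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh)
    return gm, popmap, sgmap, truth


# ---------------------------------------------------------------------------
# expression panel
# ---------------------------------------------------------------------------


def simulate_expression(
    cfg: ExpressionSimConfig,
    seed: int = 1,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, ExpressionTable], SyntelogTripletSet, dict]:
    """Homoeolog-triplet expression counts with planted bias.

    Per organ, each triplet draws a log-normal baseline expression level
    shared by its three homoeologs; planted biased triplets multiply the
    target subgenome's level by 2^effect.  Counts are negative-binomial
    around level × length × library share.  Returns
    ``(organ → ExpressionTable, triplet set, truth record)``.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_triplets
    anchors = [f"AT{i+1:05d}" for i in range(n)]
    gene_ids = {sg: [f"{sg}_g{i+1:05d}" for i in range(n)] for sg in SUBGENOME_LABELS}
    triplets = SyntelogTripletSet(
        table=pd.DataFrame({"anchor": anchors, **gene_ids})
    )
    lo, hi = cfg.length_range
    lengths = {
        sg: rng.integers(lo, hi + 1, size=n).astype(float) for sg in SUBGENOME_LABELS
    }

    tables: dict[str, ExpressionTable] = {}
    truth: dict = {"seed": seed, "organs": {}}
    for organ in cfg.organs:
        base = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)
        level = {sg: base.copy() for sg in SUBGENOME_LABELS}
        plan = cfg.bias_plan.get(organ)
        biased_idx: np.ndarray = np.array([], dtype=int)
        if plan is not None:
            sg_t, frac, eff = plan
            n_biased = int(round(frac * n))
            biased_idx = rng.choice(n, size=n_biased, replace=False)
            level[sg_t][biased_idx] *= 2.0**eff
        all_ids: list[str] = []
        all_lengths: list[float] = []
        mu_parts = []
        for sg in SUBGENOME_LABELS:
            all_ids.extend(gene_ids[sg])
            all_lengths.extend(lengths[sg])
            mu_parts.append(level[sg] * lengths[sg])
        rho = np.concatenate(mu_parts)
        mu = cfg.library_size * rho / rho.sum()
        lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
        counts = rng.poisson(lam).astype(float)
        tables[organ] = ExpressionTable.from_counts(
            all_ids, counts, all_lengths, label=organ
        )
        truth["organs"][organ] = {
            "plan": list(plan) if plan is not None else None,
            "biased_anchors": [anchors[i] for i in sorted(biased_idx)],
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        triplets.to_tsv(out / "triplets.tsv")
        manifest_rows = []
        for organ, tab in tables.items():
            path = out / f"counts_{organ}.tsv"
            tab.to_tsv(path)
            # bare filename: organ manifests resolve relative paths against
            # their own directory, which keeps the output tree relocatable
            manifest_rows.append({"organ": organ, "path": path.name})
        pd.DataFrame(manifest_rows).to_csv(out / "organs.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh)
    return tables, triplets, truth


# ---------------------------------------------------------------------------
# genome FASTA
# ---------------------------------------------------------------------------


def simulate_genome_fasta(
    cfg: GenomeSimConfig,
    seed: int = 1,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, str], SubgenomeMap, dict]:
    """Random genome with planted telomeric repeats and N-gaps.

    Telomere repeats are planted as exact tandem motif copies at the very
    start (forward orientation) and reverse-complement copies at the very
    end; the flanking base is forced off-motif so the planted run length is
    exact.  Gap runs are planted per the plan; overlapping or adjacent
    planned gaps are rejected so the plan equals the realized region count.
    """
    rng = np.random.default_rng(seed)
    motif = cfg.telomere_motif.upper()
    from .genomestats import reverse_complement

    rc = reverse_complement(motif)
    m = len(motif)
    seqs: dict[str, str] = {}
    assignment: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for plan in cfg.chromosomes:
        ln = plan.length
        start_bp = plan.telomere_start_copies * m
        end_bp = plan.telomere_end_copies * m
        if start_bp + end_bp + 2 > ln:
            raise ValidationError(
                f"{plan.name}: planted telomeres exceed chromosome length"
            )
        seq = rng.choice(list("ACGT"), size=ln)
        if plan.telomere_start_copies:
            seq[:start_bp] = list(motif * plan.telomere_start_copies)
            # force the next base off-motif so the run length is exact
            seq[start_bp] = "C" if motif[0] != "C" else "G"
        if plan.telomere_end_copies:
            seq[ln - end_bp :] = list(rc * plan.telomere_end_copies)
            seq[ln - end_bp - 1] = "G" if rc[-1] != "G" else "C"
        gaps = sorted(plan.gaps)
        prev_end = 0
        for gstart, glen in gaps:
            gend = gstart + glen - 1
            if gstart < 1 or gend > ln:
                raise ValidationError(f"{plan.name}: planted gap exceeds chromosome")
            if gstart <= start_bp + 1 or gend >= ln - end_bp:
                raise ValidationError(f"{plan.name}: planted gap overlaps telomere")
            if gstart <= prev_end + 1:
                raise ValidationError(f"{plan.name}: planned gaps overlap or touch")
            seq[gstart - 1 : gend] = "N"
            prev_end = gend
        seqs[plan.name] = "".join(seq)
        assignment[plan.name] = plan.subgenome
        lengths[plan.name] = ln
    sgmap = SubgenomeMap(assignment=assignment, lengths=lengths)
    truth = {
        "seed": seed,
        "plans": [dataclasses.asdict(p) for p in cfg.chromosomes],
        "motif": motif,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fasta", "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        sgmap.to_tsv(out / "sgmap.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh)
    return seqs, sgmap, truth
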
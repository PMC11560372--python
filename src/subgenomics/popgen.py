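"""SNP filtering and subgenome-resolved diversity statistics.

This module implements the variant-level half of the toolkit: reading
diploid genotype calls from VCF into a compact matrix, the filter cascade
(read-depth outliers, biallelic/heterozygosity/missingness, windowed LD
pruning, minor-allele-frequency), and the population-genetic summaries
computed from the retained sites — per-site and windowed nucleotide
diversity (π), per-individual heterozygosity, Weir–Cockerham F_ST, and a
genotype PCA — each aggregatable genome-wide, per chromosome, and per
subgenome of an allopolyploid reference.

Genotype codes are diploid dosages of the alternate allele:
``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.
Coordinates are 1-based inclusive internally (VCF convention); BED-style
output columns are converted to 0-based half-open at write time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("subgenomics")

MISSING = -1
GENOTYPE_CODES = (0, 1, 2, MISSING)

#: default subgenome labels of the hexaploid reference
SUBGENOME_LABELS = ("SG1", "SG2", "SG3")


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a GenotypeMatrix."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SubgenomeMap:
    """Chromosome → subgenome assignment with chromosome lengths (bp)."""

    assignment: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)
    labels: tuple[str, ...] = SUBGENOME_LABELS

    def __post_init__(self) -> None:
        bad = {sg for sg in self.assignment.values() if sg not in self.labels}
        if bad:
            raise ValidationError(
                f"subgenome labels {sorted(bad)} not in configured set {self.labels}"
            )

    def subgenome(self, chrom: str) -> str:
        try:
            return self.assignment[chrom]
        except KeyError:
            raise ValidationError(f"chromosome {chrom!r} missing from subgenome map") from None

    def chromosomes(self, label: str) -> list[str]:
        return [c for c, sg in self.assignment.items() if sg == label]

    @classmethod
    def from_tsv(cls, path: str | Path, labels: tuple[str, ...] = SUBGENOME_LABELS) -> "SubgenomeMap":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        assignment = dict(zip(df["chrom"], df["subgenome"]))
        lengths = (
            dict(zip(df["chrom"], df["length_bp"].astype(int)))
            if "length_bp" in cols
            else {}
        )
        return cls(assignment=assignment, lengths=lengths, labels=labels)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"chrom": c, "subgenome": sg, "length_bp": self.lengths.get(c, 0)}
            for c, sg in self.assignment.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Sites × samples diploid genotype calls with per-site metadata.

    ``sites`` is a DataFrame with columns ``chrom, pos, ref, alts`` (``alts``
    a tuple of alt-allele strings); ``calls`` is an int8 array of genotype
    codes; ``depths``, when present, holds per-call read depth.
    """

    sites: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise ValidationError(
                f"calls shape {self.calls.shape} != (n_sites={len(self.sites)}, "
                f"n_samples={len(self.samples)})"
            )
        if self.depths is not None:
            self.depths = np.asarray(self.depths)
            if self.depths.shape != self.calls.shape:
                raise ValidationError("depths shape differs from calls shape")
            if self.depths.size and self.depths.min() < 0:
                raise ValidationError("depths must be non-negative")
        if self.calls.size and not np.isin(self.calls, GENOTYPE_CODES).all():
            raise ValidationError("genotype codes must be in {0, 1, 2, -1}")
        pos = self.sites["pos"].to_numpy()
        for chrom, idx in self.sites.groupby("chrom", sort=False).indices.items():
            p = pos[idx]
            if np.any(np.diff(p) <= 0):
                raise ValidationError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def dosages(self) -> np.ndarray:
        """Calls as float alt-allele dosage, missing → NaN."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            calls=self.calls[mask],
            depths=None if self.depths is None else self.depths[mask],
        )

    def site_key(self) -> list[tuple[str, int]]:
        return list(zip(self.sites["chrom"], self.sites["pos"]))


@dataclass
class DiversityResult:
    """Windowed π plus per-chromosome / per-subgenome / genome aggregates."""

    windows: pd.DataFrame  # chrom, start, end, n_sites, sum_site_pi, pi_per_bp
    skipped_sites: int = 0

    def per_chromosome(self) -> pd.Series:
        w = self.windows
        span = w["end"] - w["start"] + 1
        return w.assign(span=span).groupby("chrom").apply(
            lambda g: g["sum_site_pi"].sum() / g["span"].sum(), include_groups=False
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.windows.copy()
        out["start0"] = out["start"] - 1  # BED convention: 0-based half-open
        out["end0"] = out["end"]
        out = out[["chrom", "start0", "end0", "n_sites", "pi_per_bp"]]
        out["pi_per_bp"] = out["pi_per_bp"].map(lambda v: f"{v:.6g}")
        out.to_csv(path, sep="\t", index=False)


@dataclass
class HetResult:
    """Per-sample heterozygosity, genome-wide and per subgenome."""

    table: pd.DataFrame  # index sample; columns H_genome, H_<SG>..., n_nonmissing
    undefined_samples: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        for c in out.columns:
            if c.startswith("H"):
                out[c] = out[c].map(lambda v: f"{v:.6g}" if pd.notna(v) else "NA")
        out.to_csv(path, sep="\t", index_label="sample")


@dataclass
class FstResult:
    """Weir–Cockerham variance components and F_ST for one population pair."""

    pair: tuple[str, str]
    a: np.ndarray  # among-population component per site
    b: np.ndarray  # among-individual-within-population component
    c: np.ndarray  # within-individual component
    used: np.ndarray  # sites entering the ratio sums

    @property
    def weighted_fst(self) -> float:
        """Ratio-of-sums estimator Σa / Σ(a+b+c) (VCFtools "weighted Fst")."""
        denom = (self.a + self.b + self.c)[self.used]
        if denom.size == 0:
            return math.nan
        return float(self.a[self.used].sum() / denom.sum())

    @property
    def mean_fst(self) -> float:
        """Mean of per-site ratios (diagnostic; noisier than weighted)."""
        denom = self.a + self.b + self.c
        ok = self.used & (denom != 0)
        if not ok.any():
            return math.nan
        return float(np.mean(self.a[ok] / denom[ok]))


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, plain or bgzipped) into a :class:`GenotypeMatrix`.

    Genotypes are mapped from GT regardless of phasing separator; half-missing
    or untyped calls become missing.  FORMAT/DP, when present, populates
    ``depths`` (missing DP entries become 0).  Duplicate (chrom, pos) records
    are an error.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib errors are opaque strings
        raise VcfParseError(f"{path}: cannot open/parse VCF header: {exc}") from exc

    samples = list(vcf.samples)
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    call_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    have_depth = "##FORMAT=<ID=DP" in vcf.raw_header
    seen: set[tuple[str, int]] = set()

    try:
        for rec_idx, v in enumerate(vcf, start=1):
            key = (v.CHROM, v.POS)
            if key in seen:
                raise VcfParseError(
                    f"{path}: duplicate site {v.CHROM}:{v.POS} at record {rec_idx}"
                )
            seen.add(key)
            row = np.full(len(samples), MISSING, dtype=np.int8)
            for j, g in enumerate(v.genotypes):
                a1, a2 = g[0], g[1] if len(g) > 2 else -1
                if a1 < 0 or a2 < 0:
                    continue  # untyped or half-missing
                if a1 == a2:
                    row[j] = 0 if a1 == 0 else 2
                else:
                    row[j] = 1
            chroms.append(v.CHROM)
            positions.append(v.POS)
            refs.append(v.REF)
            alts.append(tuple(v.ALT))
            call_rows.append(row)
            if have_depth:
                dp = v.format("DP")
                if dp is not None:
                    d = dp.reshape(-1).astype(np.int64)
                    d[d < 0] = 0
                    depth_rows.append(d)
                else:
                    depth_rows.append(np.zeros(len(samples), dtype=np.int64))
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"{path}: malformed record near record {len(chroms) + 1}: {exc}"
        ) from exc

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": np.array(positions, dtype=np.int64),
         "ref": refs, "alts": alts}
    )
    calls = (
        np.array(call_rows, dtype=np.int8)
        if call_rows
        else np.empty((0, len(samples)), dtype=np.int8)
    )
    depths = (
        np.array(depth_rows, dtype=np.int64)
        if (have_depth and depth_rows)
        else None
    )
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls, depths=depths)


def write_vcf(gm: GenotypeMatrix, path: str | Path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as plain-text VCF v4.2 (GT, plus DP if present)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=subgenomics\n")
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fmt = "GT"
        if gm.depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fmt = "GT:DP"
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for i in range(gm.n_sites):
            s = gm.sites.iloc[i]
            alt = ",".join(s["alts"]) if s["alts"] else "."
            cells = []
            for j in range(gm.n_samples):
                g = gt_str[int(gm.calls[i, j])]
                if gm.depths is not None:
                    g = f"{g}:{int(gm.depths[i, j])}"
                cells.append(g)
            fh.write(
                f"{s['chrom']}\t{int(s['pos'])}\t.\t{s['ref']}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------


def filter_depth_outliers(gm: GenotypeMatrix, factor: float = 10.0) -> GenotypeMatrix:
    """Drop sites whose mean cross-sample depth exceeds ``factor`` × the
    overall mean depth.

    The depth-outlier rule removes regions one order of magnitude above
    average coverage (collapsed repeats, abnormal mapping); it is applied at
    the finest resolution available here — per site.
    """
    if gm.depths is None:
        raise ValidationError(
            "genotype matrix carries no depths; skip the depth-outlier stage"
        )
    if gm.n_sites == 0:
        return gm.subset_sites(np.zeros(0, dtype=bool) == False)  # noqa: E712
    overall = gm.depths.mean()
    site_mean = gm.depths.mean(axis=1)
    keep = site_mean <= factor * overall
    logger.info("depth filter: %d/%d sites retained", keep.sum(), gm.n_sites)
    return gm.subset_sites(keep)


def filter_sites(
    gm: GenotypeMatrix,
    max_site_het: float = 0.5,
    max_missing: float = 0.10,
) -> GenotypeMatrix:
    """Retain biallelic SNPs with het fraction < ``max_site_het`` and missing
    fraction < ``max_missing`` (both strict, matching the stated cutoffs
    "<0.5 heterozygosity and < 10% missing data")."""
    if gm.n_sites == 0:
        return gm
    biallelic = np.array([len(a) == 1 for a in gm.sites["alts"]])
    n_missing = (gm.calls == MISSING).sum(axis=1)
    n_nonmiss = gm.n_samples - n_missing
    n_het = (gm.calls == 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        het_frac = np.where(n_nonmiss > 0, n_het / np.maximum(n_nonmiss, 1), 1.0)
    miss_frac = n_missing / gm.n_samples if gm.n_samples else np.ones(gm.n_sites)
    keep = biallelic & (het_frac < max_site_het) & (miss_frac < max_missing)
    logger.info("site filter: %d/%d sites retained", keep.sum(), gm.n_sites)
    return gm.subset_sites(keep)


def _maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site minor allele frequency from non-missing allele counts."""
    for i, a in enumerate(gm.sites["alts"]):
        if len(a) != 1:
            raise ValidationError(
                f"site {gm.sites['chrom'][i]}:{gm.sites['pos'][i]} is not biallelic; "
                "run filter_sites first"
            )
    nonmiss = gm.calls != MISSING
    alt = np.where(nonmiss, gm.calls, 0).sum(axis=1)
    total = 2 * nonmiss.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, alt / np.maximum(total, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def maf_filter(
    gm: GenotypeMatrix,
    threshold: float = 0.1,
    mode: str = "drop_above",
) -> GenotypeMatrix:
    """Minor-allele-frequency filter.

    ``mode='drop_above'`` removes sites with MAF strictly greater than
    ``threshold`` (the literal reading of "filter out all sites with minor
    allele frequencies over 0.1"); ``mode='drop_below'`` removes MAF strictly
    below it (the conventional rare-variant filter).  Sites with no
    non-missing calls are retained by either mode (MAF undefined).
    """
    if mode not in ("drop_above", "drop_below"):
        raise ValidationError(f"unknown maf mode {mode!r}")
    if gm.n_sites == 0:
        return gm
    maf = _maf(gm)
    with np.errstate(invalid="ignore"):
        drop = maf > threshold if mode == "drop_above" else maf < threshold
    drop = np.where(np.isnan(maf), False, drop)
    keep = ~drop
    logger.info("MAF filter (%s %g): %d/%d sites retained", mode, threshold, keep.sum(), gm.n_sites)
    return gm.subset_sites(keep)


def ld_r2(
    dosages_a: Sequence[float] | np.ndarray,
    dosages_b: Sequence[float] | np.ndarray,
    return_defined: bool = False,
) -> float | tuple[float, bool]:
    """Genotypic r²: squared Pearson correlation of alt-allele dosages over
    pairwise-complete samples.

    Missing entries may be coded -1 or NaN.  If fewer than two complete pairs
    remain, or either vector is constant, r² is undefined and reported as 0
    (with ``defined=False`` when ``return_defined``).
    """
    a = np.asarray(dosages_a, dtype=float).copy()
    b = np.asarray(dosages_b, dtype=float).copy()
    if a.shape != b.shape:
        raise ValidationError("dosage vectors differ in length")
    a[a == MISSING] = np.nan
    b[b == MISSING] = np.nan
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        return (0.0, False) if return_defined else 0.0
    r = np.corrcoef(a, b)[0, 1]
    r2 = float(r * r)
    return (r2, True) if return_defined else r2


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.4,
    window_sites: int = 50,
    step_sites: int = 5,
) -> GenotypeMatrix:
    """Windowed greedy LD pruning per chromosome.

    Within each window of ``window_sites`` consecutive sites, while any
    retained pair has r² > ``r2_max``, the later-position site of the
    (first, in position order) offending pair is dropped; the window then
    slides by ``step_sites``.  After pruning, no retained pair within any
    window exceeds ``r2_max``.
    """
    if window_sites < 2:
        raise ValidationError("window_sites must be >= 2")
    if gm.n_sites == 0:
        return gm
    dos = gm.dosages()
    keep = np.ones(gm.n_sites, dtype=bool)
    for chrom, idx in gm.sites.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        n = idx.size
        start = 0
        while start < n:
            win = idx[start : start + window_sites]
            live = [i for i in win if keep[i]]
            changed = True
            while changed:
                changed = False
                for ii in range(len(live)):
                    for jj in range(ii + 1, len(live)):
                        si, sj = live[ii], live[jj]
                        if not (keep[si] and keep[sj]):
                            continue
                        if ld_r2(dos[si], dos[sj]) > r2_max:
                            keep[sj] = False
                            live = [i for i in live if keep[i]]
                            changed = True
                            break
                    if changed:
                        break
            if start + window_sites >= n:
                break
            start += step_sites
    logger.info("LD prune (r2>%g): %d/%d sites retained", r2_max, keep.sum(), gm.n_sites)
    return gm.subset_sites(keep)


# ---------------------------------------------------------------------------
# diversity / heterozygosity / differentiation
# ---------------------------------------------------------------------------


def site_pi(calls_at_site: Sequence[int] | np.ndarray) -> float | None:
    """Per-site nucleotide diversity for a biallelic site.

    With ``n_ref`` and ``n_alt`` alleles counted over non-missing diploid
    calls and ``N = n_ref + n_alt``::

        π_site = n_ref · n_alt / (N·(N−1)/2)

    i.e. the mean pairwise difference over all C(N, 2) haplotype pairs.
    Returns ``None`` (site skipped) when fewer than two alleles are observed.
    """
    c = np.asarray(calls_at_site)
    nonmiss = c != MISSING
    n_alt = int(c[nonmiss].sum())
    big_n = 2 * int(nonmiss.sum())
    if big_n < 2:
        return None
    n_ref = big_n - n_alt
    return (n_ref * n_alt) / (big_n * (big_n - 1) // 2)


def _site_pi_vector(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized π per site; returns (pi, valid-mask)."""
    nonmiss = gm.calls != MISSING
    n_alt = np.where(nonmiss, gm.calls, 0).sum(axis=1).astype(np.int64)
    big_n = 2 * nonmiss.sum(axis=1).astype(np.int64)
    valid = big_n >= 2
    n_ref = big_n - n_alt
    denom = np.where(valid, big_n * (big_n - 1) // 2, 1)
    pi = np.where(valid, (n_ref * n_alt) / denom, 0.0)
    return pi, valid


def windowed_pi(
    gm: GenotypeMatrix,
    window_bp: int,
    lengths: Mapping[str, int] | None = None,
) -> DiversityResult:
    """Tile non-overlapping windows from position 1 and accumulate site π.

    Window π-per-bp divides the summed per-site π by the full window span:
    monomorphic positions contribute zero difference but full length to the
    denominator.  The trailing partial window uses its actual bp span.
    Chromosome lengths (when given, e.g. from a :class:`SubgenomeMap`) set
    the tiling extent; otherwise the last variant position does.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    pi, valid = _site_pi_vector(gm) if gm.n_sites else (np.zeros(0), np.zeros(0, bool))
    skipped = int((~valid).sum())
    rows = []
    for chrom, idx in gm.sites.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        pos = gm.sites["pos"].to_numpy()[idx]
        chrom_len = int(lengths[chrom]) if lengths and chrom in lengths else int(pos.max())
        n_windows = max(1, math.ceil(chrom_len / window_bp))
        win_of_site = (pos - 1) // window_bp
        for w in range(n_windows):
            start = w * window_bp + 1
            end = min((w + 1) * window_bp, chrom_len)
            sel = idx[(win_of_site == w)]
            sel_valid = sel[valid[sel]]
            s = float(pi[sel_valid].sum())
            span = end - start + 1
            rows.append(
                {"chrom": chrom, "start": start, "end": end,
                 "n_sites": int(sel_valid.size), "sum_site_pi": s,
                 "pi_per_bp": s / span}
            )
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "sum_site_pi", "pi_per_bp"]
    )
    if skipped:
        logger.info("windowed_pi: skipped %d sites with <2 called alleles", skipped)
    return DiversityResult(windows=windows, skipped_sites=skipped)


def aggregate_pi(
    dr: DiversityResult,
    sgmap: SubgenomeMap,
    weights: str = "bp",
) -> dict[str, float]:
    """Aggregate windowed π to subgenome and genome level.

    ``weights='bp'`` (default) weights each window by its bp span, so the
    aggregate is total pairwise diversity per bp; ``weights='sites'`` weights
    by variant-site count.  Empty subgenomes are reported as NaN, never 0.
    """
    if weights not in ("bp", "sites"):
        raise ValidationError(f"unknown weighting {weights!r}")
    w = dr.windows
    for chrom in w["chrom"].unique():
        sgmap.subgenome(chrom)  # raises if unmapped
    span = (w["end"] - w["start"] + 1).to_numpy(dtype=float)
    wt = span if weights == "bp" else w["n_sites"].to_numpy(dtype=float)
    contrib = w["pi_per_bp"].to_numpy() * wt
    sg_of_window = w["chrom"].map(sgmap.assignment).to_numpy()
    out: dict[str, float] = {}
    for sg in sgmap.labels:
        sel = sg_of_window == sg
        out[sg] = float(contrib[sel].sum() / wt[sel].sum()) if wt[sel].sum() > 0 else math.nan
    out["genome"] = float(contrib.sum() / wt.sum()) if wt.sum() > 0 else math.nan
    return out


def individual_heterozygosity(gm: GenotypeMatrix, sgmap: SubgenomeMap | None = None) -> HetResult:
    """Per-sample heterozygosity H = het calls / non-missing calls over the
    retained SNP sites, genome-wide and (when a map is given) per subgenome."""
    groups: dict[str, np.ndarray] = {"genome": np.ones(gm.n_sites, dtype=bool)}
    if sgmap is not None:
        sg_of_site = gm.sites["chrom"].map(sgmap.assignment)
        if sg_of_site.isna().any():
            missing = sorted(gm.sites["chrom"][sg_of_site.isna()].unique())
            raise ValidationError(f"chromosomes {missing} missing from subgenome map")
        for sg in sgmap.labels:
            groups[sg] = (sg_of_site == sg).to_numpy()
    cols: dict[str, np.ndarray] = {}
    for name, mask in groups.items():
        sub = gm.calls[mask]
        het = (sub == 1).sum(axis=0)
        nonmiss = (sub != MISSING).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[f"H_{name}"] = np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)
        if name == "genome":
            cols["n_nonmissing"] = nonmiss
    table = pd.DataFrame(cols, index=pd.Index(gm.samples, name="sample"))
    undefined = [s for s, v in zip(gm.samples, np.isnan(cols["H_genome"])) if v]
    if undefined:
        logger.warning("heterozygosity undefined for samples: %s", undefined)
    return HetResult(table=table, undefined_samples=undefined)


def wc_fst(
    gm: GenotypeMatrix,
    pops: Mapping[str, str],
    pair: tuple[str, str],
) -> FstResult:
    """Two-population Weir & Cockerham (1984) F_ST.

    Per biallelic site, variance components are computed from the two
    populations' sample sizes, alt-allele frequencies and observed
    heterozygote frequencies:

    - ``a`` — among populations,
    - ``b`` — among individuals within populations,
    - ``c`` — within individuals;

    the weighted estimate is Σa / Σ(a+b+c) over sites where the denominator
    is non-zero (the ratio-of-sums form reported by VCFtools).
    """
    labels = set(pops.values())
    for lab in pair:
        if lab not in labels:
            raise ValidationError(f"unknown population label {lab!r}")
    cols = [
        np.array([j for j, s in enumerate(gm.samples) if pops.get(s) == lab])
        for lab in pair
    ]
    for lab, c in zip(pair, cols):
        if c.size < 2:
            raise ValidationError(f"population {lab!r} has fewer than 2 samples")
    r = 2
    n_i = np.empty((gm.n_sites, r))
    p_i = np.empty((gm.n_sites, r))
    h_i = np.empty((gm.n_sites, r))
    for k, c in enumerate(cols):
        sub = gm.calls[:, c]
        nonmiss = sub != MISSING
        n = nonmiss.sum(axis=1).astype(float)
        alt = np.where(nonmiss, sub, 0).sum(axis=1).astype(float)
        het = (sub == 1).sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i[:, k] = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
            h_i[:, k] = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        n_i[:, k] = n
    ok = (n_i > 0).all(axis=1) & (n_i.sum(axis=1) > 2)
    n_sum = n_i.sum(axis=1)
    n_bar = n_sum / r
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (n_sum - (n_i**2).sum(axis=1) / n_sum) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=1) / n_sum
        s2 = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=1) / n_sum
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c_comp = h_bar / 2.0
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    c_comp = np.where(ok, c_comp, 0.0)
    used = ok & ((a + b + c_comp) != 0)
    if not used.any():
        logger.warning("wc_fst: no contributing sites for pair %s", pair)
    return FstResult(pair=pair, a=a, b=b, c=c_comp, used=used)


def pairwise_fst(
    gm: GenotypeMatrix, pops: Mapping[str, str]
) -> pd.DataFrame:
    """Weighted and mean-of-ratios F_ST for every unordered population pair."""
    labels = sorted(set(pops.values()))
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            res = wc_fst(gm, pops, (labels[i], labels[j]))
            rows.append(
                {"pop1": labels[i], "pop2": labels[j],
                 "weighted_fst": res.weighted_fst, "mean_fst": res.mean_fst,
                 "n_sites": int(res.used.sum())}
            )
    return pd.DataFrame(rows)


def genotype_pca(gm: GenotypeMatrix, n_components: int = 2):
    """PCA of the mean-imputed, centered dosage matrix (samples × sites).

    Returns ``(coordinates, explained_variance_ratio, components)``; axes are
    orthonormal.  Plumbing for population-structure visualisation.
    """
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise ValidationError("PCA needs at least 2 samples and 2 sites")
    if n_components > min(gm.n_samples, gm.n_sites):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_samples, n_sites)"
        )
    from sklearn.decomposition import PCA

    x = gm.dosages().T  # samples × sites
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(x)
    return coords, pca.explained_variance_ratio_, pca.components_


# ---------------------------------------------------------------------------
# cascade convenience
# ---------------------------------------------------------------------------


def run_filter_cascade(
    gm: GenotypeMatrix,
    depth_factor: float = 10.0,
    max_site_het: float = 0.5,
    max_missing: float = 0.10,
    r2_max: float = 0.4,
    window_sites: int = 50,
    step_sites: int = 5,
    maf_threshold: float = 0.1,
    maf_mode: str = "drop_above",
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Full filter cascade in pipeline order: depth outliers → biallelic/het/
    missingness → LD pruning → MAF.  Returns the filtered matrix and the
    per-stage survivor log."""
    log: dict[str, int] = {"input": gm.n_sites}
    if gm.depths is not None:
        gm = filter_depth_outliers(gm, factor=depth_factor)
        log["depth"] = gm.n_sites
    else:
        logger.info("no depths present; depth-outlier stage skipped")
        log["depth"] = gm.n_sites
    gm = filter_sites(gm, max_site_het=max_site_het, max_missing=max_missing)
    log["site_filters"] = gm.n_sites
    gm = ld_prune(gm, r2_max=r2_max, window_sites=window_sites, step_sites=step_sites)
    log["ld_prune"] = gm.n_sites
    gm = maf_filter(gm, threshold=maf_threshold, mode=maf_mode)
    log["maf"] = gm.n_sites
    return gm, log
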
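"""Homoeolog expression bias and subgenome dominance over 1:1:1 syntelogs.

In an allohexaploid, each ancestral gene is ideally retained as a triplet of
homoeologs, one per subgenome.  Given strictly enforced 1:1:1 syntelog
triplets and per-organ expression tables, this module classifies each
homoeolog pair as biased (|log2 fold change| above a threshold) or not,
tests for subgenome-level dominance of median expression with pairwise
Wilcoxon rank tests, and compares biased-homoeolog counts against equal
proportions with a chi-squared goodness-of-fit test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import SUBGENOME_LABELS, ValidationError

logger = logging.getLogger("subgenomics")

PAIRS = (("SG1", "SG2"), ("SG1", "SG3"), ("SG2", "SG3"))

CATEGORY_BIASED_FIRST = "biased-first"
CATEGORY_BIASED_SECOND = "biased-second"
CATEGORY_UNBIASED = "unbiased"
CATEGORY_NOT_TESTABLE = "not-testable"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SyntelogTripletSet:
    """Strict 1:1:1 homoeolog triplets (anchor, SG1, SG2, SG3 gene ids)."""

    table: pd.DataFrame  # columns: anchor, SG1, SG2, SG3

    def __post_init__(self) -> None:
        need = ["anchor", *SUBGENOME_LABELS]
        missing = [c for c in need if c not in self.table.columns]
        if missing:
            raise ValidationError(f"triplet table lacks columns {missing}")
        self.table = self.table[need].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SyntelogTripletSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [_canon_col(c) for c in df.columns]
        return cls(table=df)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _canon_col(c: str) -> str:
    c = c.strip()
    low = c.lower()
    for sg in SUBGENOME_LABELS:
        if low in (sg.lower(), f"{sg.lower()}_gene", f"gene_{sg.lower()}"):
            return sg
    if low in ("anchor", "anchor_id", "at_anchor", "arabidopsis"):
        return "anchor"
    return c


@dataclass
class ExpressionTable:
    """Gene-level counts with effective lengths and TPM for one sample/organ."""

    genes: pd.DataFrame  # index gene_id; columns length_bp, count, tpm
    label: str = ""

    @classmethod
    def from_counts(
        cls,
        gene_ids: Sequence[str],
        counts: Sequence[float],
        lengths: Sequence[float],
        label: str = "",
    ) -> "ExpressionTable":
        counts = np.asarray(counts, dtype=float)
        lengths = np.asarray(lengths, dtype=float)
        tpm = counts_to_tpm(counts, lengths)
        genes = pd.DataFrame(
            {"length_bp": lengths, "count": counts, "tpm": tpm},
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return cls(genes=genes, label=label)

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        df.columns = [c.lower() for c in df.columns]
        return cls.from_counts(
            df["gene_id"], df["count"], df["length_bp"], label=label or str(path)
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.genes[["length_bp", "count"]].copy()
        out.to_csv(path, sep="\t", index_label="gene_id")

    def tpm(self) -> pd.Series:
        return self.genes["tpm"]


@dataclass
class BiasParams:
    """Thresholds of the pairwise bias classifier."""

    log2_threshold: float = 2.0
    pseudocount: float = 0.5
    min_tpm: float = 1.0

    def __post_init__(self) -> None:
        if self.log2_threshold < 0:
            raise ValidationError("log2 threshold must be non-negative")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")


@dataclass
class DominanceReport:
    """Per-organ dominance summary."""

    organ: str
    medians: dict[str, float]  # subgenome -> median log(TPM+1)
    p_raw: dict[tuple[str, str], float]
    p_holm: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]  # Holm-adjusted at alpha
    bias_counts: pd.DataFrame  # per pair: biased_first, biased_second, unbiased, not_testable
    bias_chisq: pd.DataFrame  # per pair: chi2, df, p (two biased classes)
    dominant_subgenome: str | None
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def counts_to_tpm(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Transcripts per million from raw counts and effective lengths.

    ``rate_i = count_i / length_i``; ``TPM_i = 1e6 · rate_i / Σ rate``.
    All-zero counts yield all-zero TPM.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValidationError("counts and lengths differ in shape")
    if np.any(lengths <= 0):
        raise ValidationError("effective lengths must be positive")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return 1e6 * rate / total


def enforce_triplets(pairs: pd.DataFrame) -> SyntelogTripletSet:
    """Reduce raw synteny rows to strict 1:1:1 triplets.

    Rows with any missing subgenome member are dropped; every row touching a
    duplicated subgenome gene id is dropped entirely (all copies — no
    arbitration), so each retained gene id occurs in exactly one triplet.
    """
    df = pairs.copy()
    df.columns = [_canon_col(c) for c in df.columns]
    for col in ("anchor", *SUBGENOME_LABELS):
        if col not in df.columns:
            df[col] = np.nan
    df = df.dropna(subset=list(SUBGENOME_LABELS))
    df = df[(df[list(SUBGENOME_LABELS)] != "").all(axis=1)]
    keep = np.ones(len(df), dtype=bool)
    for col in SUBGENOME_LABELS:
        dup = df[col].duplicated(keep=False).to_numpy()
        keep &= ~dup
    # a gene id reused across columns of different rows also breaks 1:1:1
    ids = pd.concat([df[c] for c in SUBGENOME_LABELS])
    counts = ids.value_counts()
    multi = set(counts[counts > 1].index)
    if multi:
        for col in SUBGENOME_LABELS:
            keep &= ~df[col].isin(multi).to_numpy()
    out = df.loc[keep].reset_index(drop=True)
    logger.info("enforce_triplets: %d/%d rows retained", len(out), len(pairs))
    return SyntelogTripletSet(table=out)


def classify_pairwise_bias(
    tpm_a: float,
    tpm_b: float,
    params: BiasParams | None = None,
) -> tuple[str, float]:
    """Classify one homoeolog pair; returns (category, log2 ratio).

    A pair is testable only if the larger TPM reaches ``min_tpm``.  The log2
    ratio uses a symmetric pseudocount; a ratio strictly greater than the
    threshold in magnitude is called biased toward the larger side.
    """
    params = params or BiasParams()
    if tpm_a < 0 or tpm_b < 0:
        raise ValidationError("TPM values must be non-negative")
    if max(tpm_a, tpm_b) < params.min_tpm:
        return CATEGORY_NOT_TESTABLE, math.nan
    num = tpm_a + params.pseudocount
    den = tpm_b + params.pseudocount
    if den == 0:
        if num == 0:
            return CATEGORY_NOT_TESTABLE, math.nan
        return CATEGORY_BIASED_FIRST, math.inf
    if num == 0:
        return CATEGORY_BIASED_SECOND, -math.inf
    # difference of logs (not log of ratio) so antisymmetry is bit-exact
    r = math.log2(num) - math.log2(den)
    if r > params.log2_threshold:
        return CATEGORY_BIASED_FIRST, r
    if r < -params.log2_threshold:
        return CATEGORY_BIASED_SECOND, r
    return CATEGORY_UNBIASED, r


def _classify_vec(
    a: np.ndarray, b: np.ndarray, params: BiasParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pair classifier; returns (category array, log2 ratio)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    testable = np.maximum(a, b) >= params.min_tpm
    num = a + params.pseudocount
    den = b + params.pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log2(num) - np.log2(den)  # ±inf when one side is zero
    r = np.where((num == 0) & (den == 0), np.nan, r)
    cat = np.full(a.shape, CATEGORY_UNBIASED, dtype=object)
    cat[r > params.log2_threshold] = CATEGORY_BIASED_FIRST
    cat[r < -params.log2_threshold] = CATEGORY_BIASED_SECOND
    cat[np.isnan(r)] = CATEGORY_NOT_TESTABLE
    cat[~testable] = CATEGORY_NOT_TESTABLE
    r = np.where(cat == CATEGORY_NOT_TESTABLE, np.nan, r)
    return cat, r


def triplet_tpm(
    triplets: SyntelogTripletSet, expr: ExpressionTable
) -> pd.DataFrame:
    """Per-triplet TPM of the three homoeologs (columns SG1, SG2, SG3)."""
    tpm = expr.tpm()
    missing = []
    for sg in SUBGENOME_LABELS:
        absent = ~triplets.table[sg].isin(tpm.index)
        missing.extend(triplets.table[sg][absent].tolist())
    if missing:
        raise ValidationError(
            f"{len(missing)} triplet genes absent from expression table: "
            f"{sorted(missing)[:10]}{'...' if len(missing) > 10 else ''}"
        )
    return pd.DataFrame(
        {sg: tpm.loc[triplets.table[sg]].to_numpy() for sg in SUBGENOME_LABELS},
        index=triplets.table["anchor"],
    )


def bias_table(
    triplets: SyntelogTripletSet,
    expr: ExpressionTable,
    params: BiasParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise bias calls plus per-pair category counts.

    Returns ``(calls, counts)``: ``calls`` has one row per triplet × pair
    with the log2 ratio and category; ``counts`` one row per pair with
    columns biased_first / biased_second / unbiased / not_testable summing
    to the triplet count.
    """
    params = params or BiasParams()
    t = triplet_tpm(triplets, expr)
    call_rows = []
    count_rows = []
    for sg_a, sg_b in PAIRS:
        cat, r = _classify_vec(t[sg_a].to_numpy(), t[sg_b].to_numpy(), params)
        call_rows.append(
            pd.DataFrame(
                {"triplet": t.index, "pair": f"{sg_a}-{sg_b}",
                 "log2fc": r, "category": cat}
            )
        )
        count_rows.append(
            {"pair": f"{sg_a}-{sg_b}",
             "first": sg_a, "second": sg_b,
             "biased_first": int((cat == CATEGORY_BIASED_FIRST).sum()),
             "biased_second": int((cat == CATEGORY_BIASED_SECOND).sum()),
             "unbiased": int((cat == CATEGORY_UNBIASED).sum()),
             "not_testable": int((cat == CATEGORY_NOT_TESTABLE).sum())}
        )
    calls = pd.concat(call_rows, ignore_index=True)
    counts = pd.DataFrame(count_rows)
    return calls, counts


def median_dominance_test(
    tpm_by_subgenome: Mapping[str, np.ndarray],
    alpha: float = 0.05,
    paired: bool = False,
) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
    """Pairwise Wilcoxon tests of subgenome expression plus medians.

    The default is the unpaired two-sample rank-sum (Mann–Whitney) test with
    exact p for small samples and a continuity-corrected normal
    approximation otherwise; ``paired=True`` uses the signed-rank test on
    triplet-matched differences.  Medians are reported on log(TPM+1)
    (natural log); rank tests are monotone-invariant so they operate on raw
    TPM.  Returns ``(medians, raw p-values per pair)``.
    """
    vecs = {sg: np.asarray(v, dtype=float) for sg, v in tpm_by_subgenome.items()}
    n = {len(v) for v in vecs.values()}
    if len(n) != 1:
        raise ValidationError("subgenome TPM vectors differ in length")
    if n.pop() < 2:
        raise ValidationError("need at least 2 triplets")
    medians = {sg: float(np.median(np.log1p(v))) for sg, v in vecs.items()}
    pvals: dict[tuple[str, str], float] = {}
    for sg_a, sg_b in PAIRS:
        if sg_a not in vecs or sg_b not in vecs:
            continue
        a, b = vecs[sg_a], vecs[sg_b]
        if paired:
            d = a - b
            if np.all(d == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
        else:
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        pvals[(sg_a, sg_b)] = p
    return medians, pvals


def holm_adjust(pvals: Mapping[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    """Holm step-down adjustment (the pairwise.wilcox.test convention)."""
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj: dict[tuple[str, str], float] = {}
    running = 0.0
    for i, (k, p) in enumerate(items):
        running = max(running, min(1.0, (m - i) * p))
        adj[k] = running
    return adj


def equal_proportion_chisq(counts: Sequence[int]) -> tuple[float, int, float]:
    """Chi-squared goodness of fit against equal proportions.

    ``expected = Σcounts / k``; returns ``(χ², df = k−1, p)``.  Used both for
    biased-homoeolog counts and for feature composition by subgenome
    (lincRNA and TE counts).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValidationError("need at least 2 categories")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValidationError("all-zero counts")
    res = stats.chisquare(counts)
    return float(res.statistic), counts.size - 1, float(res.pvalue)


def dominance_report(
    organ_tables: Mapping[str, ExpressionTable],
    triplets: SyntelogTripletSet,
    params: BiasParams | None = None,
    alpha: float = 0.05,
    paired: bool = False,
) -> dict[str, DominanceReport]:
    """Full per-organ dominance analysis.

    For each organ: per-subgenome medians of log(TPM+1), pairwise Wilcoxon
    p-values (raw and Holm-adjusted; significance flags use the adjusted
    values), pairwise bias counts, and an equal-proportion chi-squared on
    the two biased classes of each pair.  A subgenome is called dominant in
    an organ when its median exceeds both others and both of its pairwise
    tests are significant after adjustment.
    """
    if not organ_tables:
        raise ValidationError("need at least one organ expression table")
    params = params or BiasParams()
    reports: dict[str, DominanceReport] = {}
    for organ, expr in organ_tables.items():
        t = triplet_tpm(triplets, expr)
        medians, p_raw = median_dominance_test(
            {sg: t[sg].to_numpy() for sg in SUBGENOME_LABELS},
            alpha=alpha, paired=paired,
        )
        p_holm = holm_adjust(p_raw)
        significant = {k: v < alpha for k, v in p_holm.items()}
        _, counts = bias_table(triplets, expr, params)
        chisq_rows = []
        for _, row in counts.iterrows():
            two = [row["biased_first"], row["biased_second"]]
            if sum(two) > 0:
                chi2, df, p = equal_proportion_chisq(two)
            else:
                chi2, df, p = math.nan, 1, math.nan
            chisq_rows.append({"pair": row["pair"], "chi2": chi2, "df": df, "p": p})
        dominant = None
        for sg in SUBGENOME_LABELS:
            others = [o for o in SUBGENOME_LABELS if o != sg]
            pair_keys = [tuple(sorted((sg, o))) for o in others]
            if all(medians[sg] > medians[o] for o in others) and all(
                significant.get(k, False) for k in pair_keys
            ):
                dominant = sg
                break
        reports[organ] = DominanceReport(
            organ=organ,
            medians=medians,
            p_raw=p_raw,
            p_holm=p_holm,
            significant=significant,
            bias_counts=counts,
            bias_chisq=pd.DataFrame(chisq_rows),
            dominant_subgenome=dominant,
            alpha=alpha,
        )
    return reports


def report_summary(reports: Mapping[str, DominanceReport]) -> pd.DataFrame:
    """Cross-organ summary: medians, pairwise p-values, dominance flag."""
    rows = []
    for organ, rep in reports.items():
        row: dict[str, object] = {"organ": organ}
        for sg in SUBGENOME_LABELS:
            row[f"median_log_tpm1_{sg}"] = rep.medians.get(sg, math.nan)
        for (a, b), p in rep.p_raw.items():
            row[f"p_{a}_{b}"] = p
            row[f"p_holm_{a}_{b}"] = rep.p_holm[(a, b)]
            row[f"sig_{a}_{b}"] = rep.significant[(a, b)]
        row["dominant_subgenome"] = rep.dominant_subgenome or "none"
        rows.append(row)
    return pd.DataFrame(rows)
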
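"""Assembly summary rules: telomere end scans, gap content, feature composition.

Three small, self-contained genome summaries resolved by subgenome:

- a scan of chromosome ends for tandem Arabidopsis-type telomeric repeats
  (TTTAGGG), calling an end telomere-bearing when strictly more than a
  minimum number of consecutive exact copies occur within an end window;
- accounting of assembly gaps (maximal runs of N) per chromosome and
  subgenome;
- feature composition (e.g. lincRNA or TE annotations) by subgenome, with a
  chi-squared test of counts against equal proportions.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .dominance import equal_proportion_chisq
from .popgen import SubgenomeMap, ValidationError

logger = logging.getLogger("subgenomics")

TELOMERE_MOTIF = "TTTAGGG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iter_fasta(source: str | Path | Mapping[str, str]) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTA path (plain or gzip) or a dict."""
    if isinstance(source, Mapping):
        yield from source.items()
        return
    from Bio import SeqIO

    path = Path(source)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


# ---------------------------------------------------------------------------
# telomeres
# ---------------------------------------------------------------------------


@dataclass
class TelomereScan:
    """Per-chromosome telomere end status and longest repeat runs."""

    table: pd.DataFrame  # chrom, start_detected, end_detected, status, runs...

    def status_counts(self) -> dict[str, int]:
        return self.table["status"].value_counts().to_dict()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _longest_tandem_run(window: str, motif: str) -> int:
    """Longest run of consecutive exact copies of ``motif`` in ``window``."""
    pat = re.compile(f"(?:{re.escape(motif)})+")
    best = 0
    for m in pat.finditer(window):
        best = max(best, (m.end() - m.start()) // len(motif))
    return best


def scan_telomeres(
    fasta: str | Path | Mapping[str, str],
    motif: str = TELOMERE_MOTIF,
    min_repeats: int = 10,
    end_window_bp: int = 10_000,
) -> TelomereScan:
    """Scan chromosome ends for tandem telomeric repeats.

    An end is telomere-bearing when strictly more than ``min_repeats``
    consecutive exact copies of the motif — in either orientation (the motif
    or its reverse complement; assemblies differ in strand convention) —
    occur within the first/last ``end_window_bp`` of the sequence.  Matching
    is case-insensitive.  Windows longer than the sequence are truncated
    with a warning.
    """
    rc = reverse_complement(motif)
    rows = []
    for name, seq in _iter_fasta(fasta):
        if not seq:
            raise ValidationError(f"sequence {name!r} is empty")
        if end_window_bp > len(seq):
            logger.warning(
                "end window %d bp exceeds %s length %d; truncated",
                end_window_bp, name, len(seq),
            )
        w = min(end_window_bp, len(seq))
        start_win = seq[:w].upper()
        end_win = seq[-w:].upper()
        runs = {
            "start_fwd": _longest_tandem_run(start_win, motif),
            "start_rev": _longest_tandem_run(start_win, rc),
            "end_fwd": _longest_tandem_run(end_win, motif),
            "end_rev": _longest_tandem_run(end_win, rc),
        }
        start_run = max(runs["start_fwd"], runs["start_rev"])
        end_run = max(runs["end_fwd"], runs["end_rev"])
        start_det = start_run > min_repeats
        end_det = end_run > min_repeats
        status = {
            (True, True): "both",
            (True, False): "start-only",
            (False, True): "end-only",
            (False, False): "neither",
        }[(start_det, end_det)]
        rows.append(
            {"chrom": name, "start_detected": start_det, "end_detected": end_det,
             "status": status, "start_run": start_run, "end_run": end_run, **runs}
        )
    return TelomereScan(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# gaps
# ---------------------------------------------------------------------------


@dataclass
class GapReport:
    """N-gap content per chromosome, per subgenome, and genome-wide."""

    per_chromosome: pd.DataFrame  # chrom, subgenome, length_bp, n_regions, n_bp, fraction
    per_subgenome: pd.DataFrame  # subgenome, n_regions, n_bp, total_bp, fraction

    @property
    def genome_regions(self) -> int:
        return int(self.per_chromosome["n_regions"].sum())

    @property
    def genome_fraction(self) -> float:
        tot = self.per_chromosome["length_bp"].sum()
        return float(self.per_chromosome["n_bp"].sum() / tot) if tot else 0.0

    def to_tsv(self, path: str | Path) -> None:
        self.per_chromosome.to_csv(path, sep="\t", index=False)


def gap_report(
    fasta: str | Path | Mapping[str, str],
    sgmap: SubgenomeMap | None = None,
) -> GapReport:
    """Count maximal runs of N/n as assembly gaps.

    Chromosomes absent from the subgenome map aggregate under
    ``"unassigned"`` with a warning.
    """
    pat = re.compile("[Nn]+")
    rows = []
    for name, seq in _iter_fasta(fasta):
        runs = pat.findall(seq)
        n_bp = sum(len(r) for r in runs)
        if sgmap is None:
            sg = "unassigned"
        else:
            try:
                sg = sgmap.subgenome(name)
            except ValidationError:
                logger.warning("chromosome %s not in subgenome map; 'unassigned'", name)
                sg = "unassigned"
        rows.append(
            {"chrom": name, "subgenome": sg, "length_bp": len(seq),
             "n_regions": len(runs), "n_bp": n_bp,
             "fraction": n_bp / len(seq) if len(seq) else 0.0}
        )
    per_chrom = pd.DataFrame(
        rows, columns=["chrom", "subgenome", "length_bp", "n_regions", "n_bp", "fraction"]
    )
    agg = (
        per_chrom.groupby("subgenome", sort=True)
        .agg(n_regions=("n_regions", "sum"), n_bp=("n_bp", "sum"),
             total_bp=("length_bp", "sum"))
        .reset_index()
    )
    agg["fraction"] = agg["n_bp"] / agg["total_bp"]
    return GapReport(per_chromosome=per_chrom, per_subgenome=agg)


# ---------------------------------------------------------------------------
# feature composition
# ---------------------------------------------------------------------------


def read_features(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read BED (0-based half-open) or GFF3 (1-based inclusive) intervals.

    Both are normalized to 1-based inclusive ``start``/``end`` columns.
    Malformed intervals raise with the offending line number.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            f = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start0, end0 = f[0], int(f[1]), int(f[2])
                    if end0 <= start0:
                        raise ValidationError(
                            f"{path}:{lineno}: BED interval end <= start"
                        )
                    start, end = start0 + 1, end0
                    name = f[3] if len(f) > 3 else ""
                else:
                    chrom, start, end = f[0], int(f[3]), int(f[4])
                    if end < start:
                        raise ValidationError(
                            f"{path}:{lineno}: GFF3 interval end < start"
                        )
                    name = f[2]
            except (IndexError, ValueError) as exc:
                raise ValidationError(f"{path}:{lineno}: malformed record: {exc}") from exc
            rows.append({"chrom": chrom, "start": start, "end": end, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


@dataclass
class FeatureComposition:
    """Per-subgenome feature counts, bp occupancy, and equal-proportion χ²."""

    table: pd.DataFrame  # subgenome, count, feature_bp, subgenome_bp, occupancy
    chi2: float
    df: int
    p: float

    def counts(self) -> dict[str, int]:
        return dict(zip(self.table["subgenome"], self.table["count"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def feature_composition(
    features: pd.DataFrame | str | Path,
    sgmap: SubgenomeMap,
    fmt: str | None = None,
) -> FeatureComposition:
    """Feature counts and bp-occupancy fractions per subgenome.

    Counts are tested against equal proportions with a chi-squared
    goodness-of-fit test (the same test used for biased-homoeolog counts).
    Occupancy is feature bp divided by the subgenome's total bp (requires
    chromosome lengths in the map).
    """
    if not isinstance(features, pd.DataFrame):
        features = read_features(features, fmt=fmt)
    sg_col = features["chrom"].map(sgmap.assignment)
    if sg_col.isna().any():
        missing = sorted(features["chrom"][sg_col.isna()].unique())
        raise ValidationError(f"feature chromosomes {missing} not in subgenome map")
    span = features["end"] - features["start"] + 1
    df = features.assign(subgenome=sg_col, span=span)
    rows = []
    for sg in sgmap.labels:
        sel = df[df["subgenome"] == sg]
        sg_bp = sum(sgmap.lengths.get(c, 0) for c in sgmap.chromosomes(sg))
        bp = int(sel["span"].sum())
        rows.append(
            {"subgenome": sg, "count": len(sel), "feature_bp": bp,
             "subgenome_bp": sg_bp,
             "occupancy": bp / sg_bp if sg_bp else np.nan}
        )
    table = pd.DataFrame(rows)
    chi2, dof, p = equal_proportion_chisq(table["count"].to_numpy())
    return FeatureComposition(table=table, chi2=chi2, df=dof, p=p)
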
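"""Manifest-driven workflows wiring the stages into the two pipelines.

``run_popgen_workflow`` executes the SNP filter cascade in pipeline order
(depth outliers → biallelic/het/missingness → LD pruning → MAF), logging
the survivor count after every stage, then computes windowed/aggregated π,
per-individual heterozygosity, and pairwise F_ST.  ``run_dominance_workflow``
runs the per-organ homoeolog bias and dominance analysis over a triplet map
and an organ manifest.  Every run serializes its manifest (with seed and
version) alongside the outputs so it can be replayed byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .dominance import (
    BiasParams,
    ExpressionTable,
    SyntelogTripletSet,
    bias_table,
    dominance_report,
    report_summary,
)
from .popgen import (
    SubgenomeMap,
    ValidationError,
    aggregate_pi,
    individual_heterozygosity,
    pairwise_fst,
    read_vcf,
    run_filter_cascade,
    windowed_pi,
)

logger = logging.getLogger("subgenomics")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


class StageError(RuntimeError):
    """A workflow stage failed; carries the stage name and survivor log."""

    def __init__(self, stage: str, survivors: dict[str, int], cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.survivors = survivors
        self.cause = cause


@dataclass
class RunManifest:
    """Parameters and paths of one workflow run."""

    workflow: str  # "popgen" | "dominance"
    inputs: dict[str, str]
    out_dir: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 1
    version: str = __version__

    def validate(self) -> None:
        if self.workflow not in ("popgen", "dominance"):
            raise ValidationError(f"unknown workflow {self.workflow!r}")
        required = {
            "popgen": ["vcf", "popmap", "sgmap"],
            "dominance": ["triplets", "organs"],
        }[self.workflow]
        missing = [k for k in required if k not in self.inputs]
        if missing:
            raise ValidationError(f"manifest missing inputs: {missing}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ValidationError(f"input {key!r}: no such file {path}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValidationError(f"bad manifest {path}: {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


def _sidecar(manifest: RunManifest, out: Path) -> None:
    manifest.to_json(out / "run_manifest.json")


def run_popgen_workflow(manifest: RunManifest) -> dict[str, Any]:
    """Filter cascade + diversity/heterozygosity/differentiation statistics.

    Writes windowed-π, subgenome-π, heterozygosity and F_ST TSVs plus a
    survivor log; returns the survivor log and aggregate statistics.
    """
    manifest.validate()
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = manifest.params
    survivors: dict[str, int] = {}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValidationError:
            raise
        except Exception as exc:
            raise StageError(name, survivors, exc) from exc

    gm = stage("read_vcf", read_vcf, manifest.inputs["vcf"])
    popmap_df = pd.read_csv(manifest.inputs["popmap"], sep="\t", dtype=str)
    popmap = dict(zip(popmap_df.iloc[:, 0], popmap_df.iloc[:, 1]))
    sgmap = SubgenomeMap.from_tsv(manifest.inputs["sgmap"])

    gm, survivors = stage(
        "filter_cascade",
        run_filter_cascade,
        gm,
        depth_factor=p.get("depth_factor", 10.0),
        max_site_het=p.get("max_site_het", 0.5),
        max_missing=p.get("max_missing", 0.10),
        r2_max=p.get("r2_max", 0.4),
        window_sites=p.get("window_sites", 50),
        step_sites=p.get("step_sites", 5),
        maf_threshold=p.get("maf_threshold", 0.1),
        maf_mode=p.get("maf_mode", "drop_above"),
    )
    with open(out / "survivors.json", "w") as fh:
        json.dump(survivors, fh, indent=2)
    logger.info("survivor log: %s", survivors)

    result: dict[str, Any] = {"survivors": survivors}
    if gm.n_sites > 0:
        dr = stage("windowed_pi", windowed_pi, gm, p.get("window_bp", 100_000), sgmap.lengths)
        dr.to_tsv(out / "windowed_pi.tsv")
        agg = stage("aggregate_pi", aggregate_pi, dr, sgmap, p.get("pi_weights", "bp"))
        pd.DataFrame(
            [{"scope": k, "pi_per_bp": f"{v:.6g}"} for k, v in agg.items()]
        ).to_csv(out / "subgenome_pi.tsv", sep="\t", index=False)
        result["pi"] = agg
        het = stage("heterozygosity", individual_heterozygosity, gm, sgmap)
        het.to_tsv(out / "heterozygosity.tsv")
        result["mean_heterozygosity"] = float(het.table["H_genome"].mean())
        if len(set(popmap.values())) >= 2:
            fst = stage("fst", pairwise_fst, gm, popmap)
            fst_out = fst.copy()
            for c in ("weighted_fst", "mean_fst"):
                fst_out[c] = fst_out[c].map(lambda v: f"{v:.6g}")
            fst_out.to_csv(out / "fst.tsv", sep="\t", index=False)
            result["fst"] = fst
    else:
        logger.info("no sites survive the cascade; statistics skipped")
        for name in ("windowed_pi.tsv", "subgenome_pi.tsv", "heterozygosity.tsv", "fst.tsv"):
            (out / name).write_text("")
    _sidecar(manifest, out)
    return result


def run_dominance_workflow(manifest: RunManifest) -> dict[str, Any]:
    """Per-organ homoeolog bias + dominance reports and cross-organ summary."""
    manifest.validate()
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = manifest.params
    params = BiasParams(
        log2_threshold=p.get("log2_threshold", 2.0),
        pseudocount=p.get("pseudocount", 0.5),
        min_tpm=p.get("min_tpm", 1.0),
    )
    triplets = SyntelogTripletSet.from_tsv(manifest.inputs["triplets"])
    organs_df = pd.read_csv(manifest.inputs["organs"], sep="\t", dtype=str)
    base = Path(manifest.inputs["organs"]).parent
    tables: dict[str, ExpressionTable] = {}
    for _, row in organs_df.iterrows():
        path = Path(row["path"])
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise ValidationError(f"organ {row['organ']!r}: no such file {path}")
        tables[row["organ"]] = ExpressionTable.from_tsv(path, label=row["organ"])

    try:
        reports = dominance_report(
            tables, triplets, params=params,
            alpha=p.get("alpha", 0.05), paired=p.get("paired", False),
        )
    except ValidationError:
        raise
    except Exception as exc:
        raise StageError("dominance_report", {}, exc) from exc

    summary = report_summary(reports)
    summary.to_csv(out / "dominance_summary.tsv", sep="\t", index=False, float_format="%.6g")
    all_calls = []
    for organ, rep in reports.items():
        calls, _ = bias_table(triplets, tables[organ], params)
        calls.insert(0, "organ", organ)
        all_calls.append(calls)
        rep.bias_counts.assign(organ=organ).to_csv(
            out / f"bias_counts_{organ}.tsv", sep="\t", index=False
        )
    pd.concat(all_calls, ignore_index=True).to_csv(
        out / "bias_calls.tsv", sep="\t", index=False, float_format="%.6g"
    )
    report_json = {
        organ: {
            "medians": rep.medians,
            "p_raw": {f"{a}-{b}": v for (a, b), v in rep.p_raw.items()},
            "p_holm": {f"{a}-{b}": v for (a, b), v in rep.p_holm.items()},
            "significant": {f"{a}-{b}": v for (a, b), v in rep.significant.items()},
            "dominant_subgenome": rep.dominant_subgenome,
        }
        for organ, rep in reports.items()
    }
    with open(out / "dominance_report.json", "w") as fh:
        json.dump(report_json, fh, indent=2)
        fh.write("\n")
    _sidecar(manifest, out)
    return {"reports": reports, "summary": summary}
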
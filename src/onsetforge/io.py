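"""Cohort CSV dialect and TSV/JSON artifact readers and writers.

Every artifact the pipeline writes can be read back by a function in this
module, so stages are independently re-runnable and outputs round-trip.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import LOCI, Cohort, SubjectRecord
from .evaluate import EvaluationReport, MetricsRecord
from .explain import AttributionResult
from .features import CorrelationTable, SelectionResult, StepRecord

logger = logging.getLogger(__name__)

COHORT_HEADER: list[str] = ["subject_id", "sex", "aao"] + [
    f"{gene}_{allele}" for gene in LOCI for allele in ("a1", "a2")
]


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_HEADER)
        for s in cohort.subjects:
            row: list = [s.subject_id, s.sex, repr(s.aao)]
            for gene in LOCI:
                a1, a2 = s.alleles[gene]
                row.extend([a1, a2])
            writer.writerow(row)


def read_cohort(path: str | Path) -> Cohort:
    """Read and validate a cohort CSV.

    Rows with missing alleles or non-numeric AAO raise row-numbered errors;
    rows with a1 > a2 are accepted with a logged warning and the alleles
    reassigned as min/max (the shorter allele is A1 by definition).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if header != COHORT_HEADER:
            raise ValueError(
                f"{path}: malformed header; expected {COHORT_HEADER[:4]}..."
            )
        subjects: list[SubjectRecord] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(COHORT_HEADER):
                raise ValueError(f"{path} row {lineno}: expected "
                                 f"{len(COHORT_HEADER)} fields, got {len(row)}")
            subject_id, sex = row[0], row[1]
            if subject_id in seen:
                raise ValueError(f"{path} row {lineno}: duplicate subject id "
                                 f"{subject_id!r}")
            seen.add(subject_id)
            if sex not in ("M", "F"):
                raise ValueError(f"{path} row {lineno}: sex must be M or F")
            try:
                aao = float(row[2])
            except ValueError:
                raise ValueError(f"{path} row {lineno}: non-numeric AAO "
                                 f"{row[2]!r}") from None
            alleles: dict[str, tuple[int, int]] = {}
            for gi, gene in enumerate(LOCI):
                raw1, raw2 = row[3 + 2 * gi], row[4 + 2 * gi]
                try:
                    a1, a2 = int(raw1), int(raw2)
                except ValueError:
                    raise ValueError(
                        f"{path} row {lineno}: missing or non-integer allele "
                        f"at {gene}: ({raw1!r}, {raw2!r})"
                    ) from None
                if a1 > a2:
                    logger.warning(
                        "%s row %d: %s alleles (%d, %d) reordered so A1 <= A2",
                        path, lineno, gene, a1, a2,
                    )
                    a1, a2 = a2, a1
                alleles[gene] = (a1, a2)
            subjects.append(SubjectRecord(subject_id, sex, aao, alleles))
    if not subjects:
        raise ValueError(f"{path}: no subject rows")
    return Cohort(subjects=subjects, provenance={"source": str(path)})


# -- correlation tables -------------------------------------------------------

def write_correlation_tsv(table: CorrelationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_correlation_tsv(path: str | Path) -> CorrelationTable:
    df = pd.read_csv(path, sep="\t")
    return CorrelationTable(
        features=df["feature"].tolist(),
        r=df["r"].to_numpy(float),
        p=df["p"].to_numpy(float),
        n=int(df["n"].iloc[0]),
    )


# -- selection results --------------------------------------------------------

def write_selection(result: SelectionResult, path: str | Path) -> None:
    """JSON selection plus a ``.trace.tsv`` sidecar of the step trace."""
    path = Path(path)
    path.write_text(json.dumps({
        "method": result.method,
        "selected": result.selected,
    }, indent=2))
    rows = []
    for rec in result.trace:
        rows.append({
            "step": rec.step,
            "added_feature": "" if rec.feature is None else rec.feature,
            "n_candidates": rec.n_candidates,
            "cv_r2": "" if rec.cv_r2 is None else repr(rec.cv_r2),
            "improvement": "" if rec.improvement is None else repr(rec.improvement),
            "accepted": int(rec.accepted),
        })
    pd.DataFrame(
        rows, columns=["step", "added_feature", "n_candidates", "cv_r2",
                       "improvement", "accepted"],
    ).to_csv(path.with_suffix(".trace.tsv"), sep="\t", index=False)


def read_selection(path: str | Path) -> SelectionResult:
    path = Path(path)
    payload = json.loads(path.read_text())
    trace: list[StepRecord] = []
    trace_path = path.with_suffix(".trace.tsv")
    if trace_path.exists():
        df = pd.read_csv(trace_path, sep="\t", keep_default_na=False)
        for _, row in df.iterrows():
            trace.append(StepRecord(
                step=int(row["step"]),
                feature=str(row["added_feature"]) or None,
                n_candidates=int(row["n_candidates"]),
                cv_r2=float(row["cv_r2"]) if row["cv_r2"] != "" else None,
                improvement=(float(row["improvement"])
                             if row["improvement"] != "" else None),
                accepted=bool(int(row["accepted"])),
            ))
    return SelectionResult(method=payload["method"],
                           selected=payload["selected"], trace=trace)


# -- evaluation reports -------------------------------------------------------

def write_report(report: EvaluationReport, path: str | Path) -> None:
    """TSV mirror of the comparison table plus a JSON twin."""
    path = Path(path)
    report.to_frame().to_csv(path, sep="\t", index=False)
    payload = {
        "best": list(report.best) if report.best else None,
        "rows": [
            {
                "model": a, "method": m, "subset": s,
                "metrics": None if rec is None else rec.__dict__,
            }
            for (a, m, s), rec in report.rows.items()
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def read_report(path: str | Path) -> EvaluationReport:
    payload = json.loads(Path(path).with_suffix(".json").read_text())
    rows = {}
    for row in payload["rows"]:
        key = (row["model"], row["method"], row["subset"])
        rows[key] = None if row["metrics"] is None else MetricsRecord(**row["metrics"])
    best = tuple(payload["best"]) if payload["best"] else None
    return EvaluationReport(rows=rows, best=best)


# -- attributions -------------------------------------------------------------

def write_attribution(attr: AttributionResult, path: str | Path) -> None:
    """Wide TSV of contributions plus a JSON summary (base value, ranking)."""
    from .explain import importance_ranking

    path = Path(path)
    pd.DataFrame(attr.contributions, columns=attr.feature_names).to_csv(
        path, sep="\t", index=False
    )
    summary = {
        "base_value": attr.base_value,
        "estimator": attr.estimator,
        "n_permutations": attr.n_permutations,
        "background_size": attr.background_size,
        "seed": attr.seed,
        "importance": [
            {"feature": name, "mean_abs_contribution": value}
            for name, value in importance_ranking(attr)
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def read_attribution_tsv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Feature names and the contributions matrix of a written attribution."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return list(df.columns), df.to_numpy(float)


def write_dependence_tsv(pairs: np.ndarray, path: str | Path) -> None:
    pairs = np.asarray(pairs)
    with Path(path).open("w") as fh:
        fh.write("raw_value\tcontribution\n")
        for raw, contrib in pairs:
            # repr of a Python float is the shortest round-tripping form
            fh.write(f"{float(raw)!r}\t{float(contrib)!r}\n")


def read_dependence_tsv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return df[["raw_value", "contribution"]].to_numpy(float)
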
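"""Plain-text format adapters: counts TSV, sample sheet CSV, design CSV, GMT, models JSON.

All tables are written with header rows; expression matrices carry their
processing stage in a ``#stage=`` comment line so round trips preserve it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignMatrix, FactorBounds
from .errors import ParseError
from .normalize import ExpressionMatrix
from .surface import GeneResponseModel


def write_matrix(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#stage={expr.stage}\n")
        expr.data.to_csv(fh, sep="\t", index_label="gene")


def read_matrix(path) -> ExpressionMatrix:
    path = Path(path)
    stage = "raw"
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#stage="):
            stage = first.strip().split("=", 1)[1]
            data = pd.read_csv(fh, sep="\t", index_col="gene")
        else:
            fh.seek(0)
            data = pd.read_csv(fh, sep="\t", index_col=0)
    return ExpressionMatrix(data, stage)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas raises many types
        raise ParseError(f"cannot parse counts TSV: {exc}") from exc
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "run_id"}
    if not required <= set(df.columns):
        raise ParseError(f"sample sheet must contain columns {sorted(required)}")
    return df


def write_design(design: DesignMatrix, path) -> None:
    design.runs.to_csv(path, index=False)


def read_design(path, bounds: list[FactorBounds], validate_bounds: bool = True) -> DesignMatrix:
    df = pd.read_csv(path)
    design = DesignMatrix(df, list(bounds))
    if validate_bounds:
        vals = design.factor_values()
        for i, fb in enumerate(bounds):
            bad = np.flatnonzero((vals[:, i] < fb.low - 1e-9) | (vals[:, i] > fb.high + 1e-9))
            if bad.size:
                raise ParseError(
                    f"factor {fb.name} outside bounds in design", line=int(bad[0]) + 2
                )
    return design


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "") -> None:
    with Path(path).open("w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description or name] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description, >=1 gene", line=lineno)
            sets[fields[0]] = fields[2:]
    return sets


def models_to_json(models: dict[str, GeneResponseModel], bounds: list[FactorBounds], path) -> None:
    payload = {
        "bounds": [
            {"name": fb.name, "low": fb.low, "high": fb.high} for fb in bounds
        ],
        "models": {
            gene: {
                "terms": list(m.terms),
                "coef_coded": m.coef.tolist(),
                "coef_raw": m.raw_coefficients(bounds).tolist()
                if m.status == "ok"
                else None,
                "adjusted_r2": None if np.isnan(m.adjusted_r2) else m.adjusted_r2,
                "aic": None if np.isnan(m.aic) else m.aic,
                "n_obs": m.n_obs,
                "status": m.status,
            }
            for gene, m in models.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def models_from_json(path) -> tuple[dict[str, GeneResponseModel], list[FactorBounds]]:
    payload = json.loads(Path(path).read_text())
    bounds = [FactorBounds(b["name"], b["low"], b["high"]) for b in payload["bounds"]]
    models = {}
    for gene, rec in payload["models"].items():
        models[gene] = GeneResponseModel(
            gene=gene,
            terms=tuple(rec["terms"]),
            coef=np.array(rec["coef_coded"], dtype=float),
            adjusted_r2=np.nan if rec["adjusted_r2"] is None else rec["adjusted_r2"],
            aic=np.nan if rec["aic"] is None else rec["aic"],
            n_obs=rec["n_obs"],
            rss_w=np.nan,
            status=rec["status"],
        )
    return models, bounds
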
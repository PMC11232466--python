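"""Reading and writing summary statistics and result files.

Summary statistics use a tab-delimited dialect modeled on PLINK2 ``.glm``
output: header row with CHR, ID, POS, A1, A2, N and either Z_INT or
BETA_INT + SE_INT (Z is recomputed from BETA/SE when absent).  Results are
written as twin JSON + TSV files with a provenance header; the round trip is
exact for all numeric fields.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import AggregateResult
from .estimator import EstimateResult
from .gwis import GWISRecord, SummaryStats
from .ld_panel import VariantInfo

__all__ = ["read_sumstats", "write_sumstats", "write_results", "read_results"]

_REQUIRED = ("ID", "A1", "A2", "N")
_NA = "NA"


def read_sumstats(path: str) -> SummaryStats:
    """Parse a tab-delimited GWIS summary-statistics file.

    Requires columns ID, A1, A2, N and either Z_INT or both BETA_INT and
    SE_INT; CHR, POS, MAF are optional.  Duplicate IDs and non-numeric Z
    values are rejected with the offending line numbers (1-based, header
    included).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_NA], keep_default_na=False)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_z = "Z_INT" in df.columns
    if not has_z and not ("BETA_INT" in df.columns and "SE_INT" in df.columns):
        raise ValueError(f"{path}: need Z_INT or BETA_INT + SE_INT columns")

    dup = df["ID"].duplicated(keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicate variant IDs at line(s) {lines}")

    nan_col = pd.Series(np.nan, index=df.index)
    if has_z:
        z = pd.to_numeric(df["Z_INT"], errors="coerce")
        beta = pd.to_numeric(df["BETA_INT"], errors="coerce") if "BETA_INT" in df.columns else nan_col
        se = pd.to_numeric(df["SE_INT"], errors="coerce") if "SE_INT" in df.columns else nan_col
    else:
        beta = pd.to_numeric(df["BETA_INT"], errors="coerce")
        se = pd.to_numeric(df["SE_INT"], errors="coerce")
        z = beta / se
    bad = z.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise ValueError(f"{path}: non-numeric interaction Z at line(s) {lines}")
    n_col = pd.to_numeric(df["N"], errors="coerce")
    if n_col.isna().any():
        lines = (df.index[n_col.isna()] + 2).tolist()
        raise ValueError(f"{path}: non-numeric N at line(s) {lines}")

    records = []
    for i in range(len(df)):
        variant = VariantInfo(
            id=str(df["ID"].iat[i]),
            chrom=str(df["CHR"].iat[i]) if "CHR" in df.columns else "0",
            pos=int(df["POS"].iat[i]) if "POS" in df.columns else i + 1,
            a1=str(df["A1"].iat[i]),
            a2=str(df["A2"].iat[i]),
            maf=float(df["MAF"].iat[i]) if "MAF" in df.columns else 0.25,
        )
        records.append(
            GWISRecord(
                variant=variant,
                z_interaction=float(z.iat[i]),
                beta_main=0.0,
                n=int(n_col.iat[i]),
                beta_interaction=float(beta.iat[i]) if not np.isnan(beta.iat[i]) else np.nan,
                se_interaction=float(se.iat[i]) if not np.isnan(se.iat[i]) else np.nan,
            )
        )
    stats = SummaryStats(records=records, n=int(n_col.min()))
    return stats


def write_sumstats(stats: SummaryStats, path: str) -> None:
    """Write summary statistics in the tab-delimited dialect read_sumstats parses."""
    rows = []
    for r in stats.records:
        rows.append(
            {
                "CHR": r.variant.chrom,
                "ID": r.variant.id,
                "POS": r.variant.pos,
                "A1": r.variant.a1,
                "A2": r.variant.a2,
                "N": r.n,
                "BETA_INT": r.beta_interaction,
                "SE_INT": r.se_interaction,
                "Z_INT": r.z_interaction,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA)


def _provenance(seed: int | None, config: dict | None) -> dict:
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return {
        "tool": "lderge",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
    }


def write_results(
    result: EstimateResult | AggregateResult,
    prefix: str,
    seed: int | None = None,
    config: dict | None = None,
) -> tuple[str, str]:
    """Write a fit or aggregation result as ``prefix.json`` + ``prefix.tsv``.

    JSON carries every field at full precision (repr round-trip safe, so
    p-values like 1e-24 survive); the TSV is a flat human-diffable table.
    Returns the two paths written.
    """
    payload: dict = {"provenance": _provenance(seed, config)}
    if isinstance(result, EstimateResult):
        d = asdict(result)
        d["leave_one_out"] = [float(v) for v in result.leave_one_out]
        payload["estimate"] = d
        tsv_rows = [
            {
                "h2_I": result.h2_I,
                "intercept": result.intercept,
                "se": result.se,
                "p_value": result.p_value,
                "method": result.method,
                "n_blocks": result.n_blocks_jackknife,
                "m_used": result.m_used,
                "n_used": result.n_used,
            }
        ]
    elif isinstance(result, AggregateResult):
        payload["aggregate"] = {
            "total_h2_I": result.total_h2_I,
            "se": result.se,
            "p_value": result.p_value,
            "per_covariate": [
                {"name": nm, "h2_I": h, "se": s} for nm, h, s in result.per_covariate
            ],
        }
        tsv_rows = [
            {"covariate": nm, "h2_I": h, "se": s} for nm, h, s in result.per_covariate
        ]
        tsv_rows.append(
            {"covariate": "TOTAL", "h2_I": result.total_h2_I, "se": result.se}
        )
    else:
        raise TypeError(f"unsupported result type {type(result).__name__}")

    json_path, tsv_path = f"{prefix}.json", f"{prefix}.tsv"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    pd.DataFrame(tsv_rows).to_csv(tsv_path, sep="\t", index=False, na_rep=_NA)
    return json_path, tsv_path


def read_results(path: str) -> dict:
    """Read back a JSON results file written by :func:`write_results`."""
    with open(path) as fh:
        return json.load(fh)
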
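"""Readers, writers and run configuration.

The only tabular format is UTF-8 comma-delimited CSV with "." decimals:
response matrices are headerless (or single-header) 0/1 integer tables
with one row per examinee; summaries and fit statistics are written with
fixed column sets so downstream tooling can rely on the schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult, ModelFitResult, dichotomize as _dichotomize
from .model import ResponseMatrix

__all__ = ["RunConfig", "read_response_csv", "write_summary",
           "write_items_csv", "read_prior_file"]

ITEM_SUMMARY_COLUMNS = ["item", "alpha_est", "alpha_se", "beta_est", "beta_se",
                        "g_est", "g_se", "s_est", "s_se", "rhat_max"]
FIT_COLUMNS = ["model", "loglik", "n_params", "aic", "bic", "lr_chisq", "lr_df"]


@dataclass(frozen=True)
class RunConfig:
    """One fit's settings; defaults are the reference configuration."""

    model_tag: str = "4pno"
    sampler: str = "mmnuts"
    n_chains: int = 4
    n_iter: int = 2000              # warm-up is the first half
    max_depth: int = 10
    delta_max: float = 100.0        # divergence threshold
    target_accept: float = 0.8
    sqrt_k_scaling: bool = True     # dual-averaging shrinkage exponent
    ze_refresh: str = "per-gradient"  # or "per-iteration" (reference path only)
    seed: int = 0


def read_response_csv(path, dichotomize: bool = False) -> ResponseMatrix:
    """Load a dichotomous response matrix (rows = examinees).

    A single non-numeric header row is tolerated and skipped.  With
    ``dichotomize`` any category >= 1 is recoded to 1; otherwise the first
    non-0/1 cell is reported by row and column.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, header=None, dtype=str,
                          skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None

    first = raw.iloc[0]
    numeric = pd.to_numeric(first, errors="coerce")
    if numeric.isna().any():
        raw = raw.iloc[1:].reset_index(drop=True)
        if raw.empty:
            raise ValueError(f"{path}: no data rows after the header")

    values = raw.apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {r + 1}, "
            f"column {c + 1} (value {raw.iat[r, c]!r})"
        )
    if dichotomize:
        return _dichotomize(values)
    nonbinary = np.argwhere((values != 0) & (values != 1))
    if nonbinary.size:
        r, c = nonbinary[0]
        raise ValueError(
            f"{path}: non-binary cell at row {r + 1}, column {c + 1} "
            f"(value {values[r, c]!r}); pass dichotomize=True to recode"
        )
    return ResponseMatrix(values.astype(np.int8))


def write_response_csv(Y: ResponseMatrix, path) -> None:
    np.savetxt(path, Y.data, fmt="%d", delimiter=",")


def write_items_csv(items, path) -> None:
    """True/estimated item parameters as columns item, alpha, beta, g, s."""
    pd.DataFrame({
        "item": np.arange(1, items.n_items + 1),
        "alpha": items.alpha, "beta": items.beta,
        "g": items.g, "s": items.s,
    }).to_csv(path, index=False, float_format="%.10g")


def write_summary(result: FitResult, fit_stats: list[ModelFitResult] | pd.DataFrame | None,
                  summary_path, fit_path=None) -> None:
    """Write the per-item posterior summary and, optionally, fit statistics.

    The summary CSV has exactly the columns ``ITEM_SUMMARY_COLUMNS``
    (estimate and SE per parameter plus the item's largest R-hat); the fit
    CSV has ``FIT_COLUMNS``.
    """
    table = result.item_table()[ITEM_SUMMARY_COLUMNS]
    table.to_csv(summary_path, index=False, float_format="%.6g")
    if fit_stats is None:
        return
    if fit_path is None:
        raise ValueError("fit_path is required when fit statistics are given")
    if isinstance(fit_stats, pd.DataFrame):
        frame = fit_stats
    else:
        frame = pd.DataFrame([{
            "model": f.model_tag, "loglik": f.loglik, "n_params": f.n_params,
            "aic": f.aic, "bic": f.bic,
            "lr_chisq": np.nan if f.lr_chisq is None else f.lr_chisq,
            "lr_df": 0 if f.lr_df is None else f.lr_df,
        } for f in fit_stats])
    frame[FIT_COLUMNS].to_csv(fit_path, index=False, float_format="%.8g")


def read_prior_file(path) -> dict[str, tuple[float, float]]:
    """Plain-text prior table: lines ``name mean variance``.

    Names are theta, alpha_star, beta, gamma, varsigma; '#' starts a
    comment.  Returns a dict usable as ``PriorSpec(**read_prior_file(p))``.
    """
    allowed = {"theta", "alpha_star", "beta", "gamma", "varsigma"}
    out: dict[str, tuple[float, float]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace("=", " ").split()
        if len(parts) != 3 or parts[0] not in allowed:
            raise ValueError(
                f"{path}:{lineno}: expected '<name> <mean> <variance>' with "
                f"name in {sorted(allowed)}, got {line!r}"
            )
        out[parts[0]] = (float(parts[1]), float(parts[2]))
    return out
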
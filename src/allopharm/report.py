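"""Parameter-table rendering in the 'mean ± SEM (n)' house style."""

from __future__ import annotations

import math
from typing import Mapping

import pandas as pd

from .exceptions import ShapeError
from .fitting import FitResult, format_estimate

__all__ = ["render_parameter_table"]

# canonical column order; anything else is appended alphabetically
_PREFERRED = [
    "bmax", "pKd_radioligand", "pKi_agonist", "pKb_modulator", "log_alpha",
    "log_alpha_prime", "log_tau_A", "log_tau_B", "log_alphabeta",
]


def _column_key(name: str) -> str:
    return name.split("__")[0]


def render_parameter_table(results: Mapping[str, FitResult]
                           ) -> pd.DataFrame:
    """One row per fit, one column per parameter, cells 'mean ± SEM (n)'.

    Missing parameters render as 'N.D.'. Numbers are rounded half-even to
    two decimals (large integer-valued estimates such as Bmax keep thousands
    separators instead).
    """
    if not results:
        raise ShapeError("results must be non-empty")
    columns: list[str] = []
    for fit in results.values():
        for name in list(fit.estimates) + list(fit.derived):
            if name not in columns:
                columns.append(name)

    def order(c):
        base = _column_key(c)
        try:
            return (0, _PREFERRED.index(base), c)
        except ValueError:
            return (1, 0, c)

    columns.sort(key=order)
    rows = {}
    for label, fit in results.items():
        row = {}
        for col in columns:
            if col in fit.estimates:
                row[col] = format_estimate(
                    fit.estimates[col], fit.sems.get(col, math.nan),
                    fit.n_replicates.get(col))
            elif col in fit.derived:
                v, s = fit.derived[col]
                row[col] = format_estimate(v, s, None)
            else:
                row[col] = "N.D."
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
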
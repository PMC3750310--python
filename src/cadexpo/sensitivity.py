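"""Contribution-to-variance sensitivity analysis.

The convention of spreadsheet risk tools: compute the Spearman rank
correlation r_i between each stochastic input's draws and the output draws,
then report contribution_i = r_i^2 / sum_j r_j^2 * 100.  Squaring makes the
measure invariant to strictly monotone transformations of any input and
insensitive to the correlation's sign, which is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .montecarlo import SimulationResult
from .tables import ValidationError

__all__ = ["SensitivityResult", "contribution_to_variance", "sensitivity_of"]


@dataclass
class SensitivityResult:
    """Per-input rank correlations and normalized variance contributions.

    ``table`` is indexed by input label with columns ``rank_correlation``
    (signed Spearman r) and ``contribution`` (percent, summing to 100),
    sorted by descending contribution.
    """

    table: pd.DataFrame

    def contribution(self, label: str) -> float:
        return float(self.table.loc[label, "contribution"])

    def top(self, k: int = 4) -> pd.DataFrame:
        return self.table.head(k)


def contribution_to_variance(
    input_draws: dict[str, np.ndarray], output_draws: np.ndarray
) -> SensitivityResult:
    """Normalized squared-rank-correlation contribution of each input.

    Inputs with zero variance get correlation 0 and contribute nothing;
    an all-constant input set is an error (no variance to attribute).
    """
    if not input_draws:
        raise ValidationError("no inputs supplied")
    n = len(output_draws)
    if n < 10:
        raise ValidationError("need at least 10 draws for sensitivity analysis")
    rows = []
    for label, draws in input_draws.items():
        if len(draws) != n:
            raise ValidationError(
                f"input {label!r} has {len(draws)} draws, output has {n}"
            )
        if np.ptp(draws) == 0.0:
            r = 0.0
        else:
            r = float(stats.spearmanr(draws, output_draws).statistic)
        rows.append((label, r))
    total_r2 = sum(r * r for _, r in rows)
    if total_r2 == 0.0:
        raise ValidationError("all inputs constant: sensitivity undefined")
    table = pd.DataFrame(rows, columns=["input", "rank_correlation"]).set_index("input")
    table["contribution"] = 100.0 * table["rank_correlation"] ** 2 / total_r2
    table = table.sort_values("contribution", ascending=False)
    return SensitivityResult(table=table)


def sensitivity_of(result: SimulationResult) -> SensitivityResult:
    """Sensitivity of a simulation's output to its retained input draws."""
    if not result.input_draws:
        raise ValidationError(
            "simulation result retained no input draws; rerun simulate()"
        )
    return contribution_to_variance(result.input_draws, result.draws)
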
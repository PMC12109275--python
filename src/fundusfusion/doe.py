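"""Two-level full factorial design of experiments for hyperparameters.

The four tuned factors of the concatenated classifier are

    A3: ANN layers   (-1: 2,  +1: 4)
    B3: ANN nodes    (-1: 4,  +1: 16)
    C3: head layers  (-1: 2,  +1: 3)
    D3: head nodes   (-1: 4,  +1: 16)

A 2^k full factorial design enumerates every +-1 combination (16 runs
for k=4) in standard order; each run is trained with ``replicates``
independent replicates, each yielding one accuracy per block.  Main
(and optionally two-way interaction) effects are estimated by ordinary
least squares of the block accuracies on the coded factors:
``effect = mean(y | +1) - mean(y | -1) = 2 * coefficient``, with
t-values and p-values from the OLS fit.  The recommended setting takes
the +1 level for every factor with a positive coefficient, the -1 level
otherwise (ties break toward -1, the cheaper setting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class Factor:
    """A two-level factor with decoded settings for the coded levels."""

    name: str
    low_value: object
    high_value: object

    def __post_init__(self) -> None:
        if self.low_value == self.high_value:
            raise ValueError(f"factor {self.name}: levels must differ")

    def decode(self, level: int) -> object:
        return self.high_value if level > 0 else self.low_value


#: The four concatenated-model factors with their decoded settings.
DEFAULT_FACTORS = (
    Factor("A3", 2, 4),    # ANN layers
    Factor("B3", 4, 16),   # ANN nodes
    Factor("C3", 2, 3),    # head layers
    Factor("D3", 4, 16),   # head nodes
)


@dataclass(frozen=True)
class FactorialDesign:
    factors: tuple[Factor, ...]
    runs: np.ndarray = field(compare=False)  # (2^k, k) of +-1
    replicates: int = 2
    blocks_per_run: int = 5

    def decode_run(self, j: int) -> dict[str, object]:
        return {f.name: f.decode(int(l)) for f, l in zip(self.factors, self.runs[j])}


@dataclass
class RunResult:
    """Responses of one (combination, replicate) experiment."""

    combination: int
    replicate: int
    accuracies: np.ndarray | None  # one per block
    error: str | None = None

    @property
    def mean(self) -> float | None:
        return None if self.accuracies is None else float(np.mean(self.accuracies))

    @property
    def sd(self) -> float | None:
        if self.accuracies is None:
            return None
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def full_factorial(
    factors, replicates: int = 2, blocks_per_run: int = 5
) -> FactorialDesign:
    """Standard-order 2^k design; the first factor alternates fastest.

    Every column is balanced (equal +-1 counts) and any two columns are
    orthogonal.
    """
    factors = tuple(factors)
    if len(factors) < 1:
        raise ValueError("need at least one factor")
    names = [f.name for f in factors]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names in {names}")
    k = len(factors)
    runs = np.empty((2**k, k), dtype=int)
    for i in range(k):
        block = np.repeat([-1, 1], 2**i)
        runs[:, i] = np.tile(block, 2 ** (k - 1 - i))
    return FactorialDesign(
        factors=factors, runs=runs, replicates=replicates, blocks_per_run=blocks_per_run
    )


def run_design(design: FactorialDesign, experiment, seeds=None) -> list[RunResult]:
    """Execute ``replicates x 2^k`` experiments.

    ``experiment(settings: dict, seed: int) -> array of block
    accuracies``.  A failing callback is recorded in its RunResult
    (``error`` set, accuracies None) without aborting the design.
    """
    n_runs = len(design.runs)
    if seeds is None:
        seeds = [1000 * j + i for j in range(n_runs) for i in range(design.replicates)]
    seeds = list(seeds)
    if len(seeds) != n_runs * design.replicates:
        raise ValueError(f"need {n_runs * design.replicates} seeds, got {len(seeds)}")
    results = []
    s = 0
    for j in range(n_runs):
        settings = design.decode_run(j)
        for i in range(design.replicates):
            try:
                acc = np.asarray(experiment(settings, seeds[s]), dtype=float)
                results.append(RunResult(combination=j, replicate=i, accuracies=acc))
            except Exception as exc:  # recorded, not fatal
                results.append(
                    RunResult(combination=j, replicate=i, accuracies=None, error=str(exc))
                )
            s += 1
    return results


def _term_columns(design: FactorialDesign, terms) -> np.ndarray:
    """Coded column for each term; interactions are products of mains."""
    name_to_col = {f.name: design.runs[:, i] for i, f in enumerate(design.factors)}
    cols = []
    for term in terms:
        parts = term.split(":")
        col = np.ones(len(design.runs))
        for p in parts:
            if p not in name_to_col:
                raise ValueError(f"unknown factor {p!r} in term {term!r}")
            col = col * name_to_col[p]
        cols.append(col)
    return np.column_stack(cols)


def estimate_effects(
    design: FactorialDesign, results: list[RunResult], terms=None
) -> pd.DataFrame:
    """OLS effect estimates over all block accuracies.

    The response unit is one block accuracy; every stored accuracy of
    every successful replicate enters the fit.  Returns a table with
    columns Term, Effect, Coef, T-Value, p-Value (effect = 2 x coef for
    a coded +-1 design).
    """
    if terms is None:
        terms = [f.name for f in design.factors]
    ok = [r for r in results if r.accuracies is not None]
    if not ok:
        raise ValueError("no successful runs to analyze")
    coded = _term_columns(design, terms)
    rows, y = [], []
    for r in ok:
        for acc in r.accuracies:
            rows.append(coded[r.combination])
            y.append(acc)
    X = sm.add_constant(np.array(rows), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient term set; cannot estimate all requested terms")
    fit = sm.OLS(np.array(y), X).fit()
    return pd.DataFrame(
        {
            "Term": list(terms),
            "Effect": 2.0 * fit.params[1:],
            "Coef": fit.params[1:],
            "T-Value": fit.tvalues[1:],
            "p-Value": fit.pvalues[1:],
        }
    )


def select_optimum(effect_table: pd.DataFrame, factors=None) -> dict[str, dict]:
    """Recommended level per factor when maximizing the response.

    +1 for a positive coefficient, -1 otherwise (zero ties go to -1).
    Interaction terms in the table are ignored.  With ``factors``
    given, decoded settings are included.
    """
    by_name = {f.name: f for f in (factors or ())}
    out: dict[str, dict] = {}
    for _, row in effect_table.iterrows():
        term = row["Term"]
        if ":" in term:
            continue
        level = 1 if row["Coef"] > 0 else -1
        entry = {"level": level, "coef": float(row["Coef"])}
        if term in by_name:
            entry["setting"] = by_name[term].decode(level)
        out[term] = entry
    return out


def rank_combinations(design: FactorialDesign, results: list[RunResult]) -> pd.DataFrame:
    """Combinations sorted by mean accuracy (desc), ties by lower SD.

    One row per combination, pooling all block accuracies over
    replicates, with decoded factor settings.
    """
    ok = [r for r in results if r.accuracies is not None]
    if not ok:
        raise ValueError("no successful runs to rank")
    rows = []
    for j in range(len(design.runs)):
        pooled = np.concatenate(
            [r.accuracies for r in ok if r.combination == j] or [np.array([])]
        )
        if pooled.size == 0:
            continue
        row = {"combination": j + 1}
        row.update(design.decode_run(j))
        row["mean_accuracy"] = float(np.mean(pooled))
        row["sd"] = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["mean_accuracy", "sd"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table
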
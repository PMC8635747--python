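"""Pairwise Pearson correlations and greedy collinearity screening.

Before relating the climate and soil blocks, strongly collinear variables
(|r| above a threshold, 0.90 by default) are removed one at a time.  At each
step the pair with the largest |r| is examined and the member with the
*higher* number of high-correlation partners among the still-retained
variables is conserved — it stands in for the larger set of redundant
variables — while the other is eliminated.  Ties fall back to the larger sum
of |r| against retained variables, then to input column order.  Every step is
logged so the alternative rule (drop the hub instead) can be audited or
enabled with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CorrelationScreen", "pearson_matrix", "screen_collinear"]


@dataclass
class CorrelationScreen:
    """Result of the elimination procedure."""

    variables: list[str]
    matrix: pd.DataFrame
    threshold: float
    retained: list[str]
    eliminated: list[str]
    log: pd.DataFrame  # step, var_a, var_b, r, eliminated, conserved, tie_count, tie_sum

    def retained_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[self.retained, self.retained]

    def write(self, out_dir: str | Path, prefix: str = "screen") -> None:
        out = Path(out_dir)
        self.matrix.to_csv(out / f"{prefix}_correlations.csv")
        self.log.to_csv(out / f"{prefix}_log.csv", index=False)
        (out / f"{prefix}_retained.txt").write_text("\n".join(self.retained) + "\n")


def pearson_matrix(env: pd.DataFrame) -> pd.DataFrame:
    """Product-moment correlation matrix on complete cases.

    Requires at least 3 complete rows and nonzero variance in every column.
    """
    data = env.dropna()
    if len(data) < 3:
        raise ValueError(f"need >= 3 complete rows, have {len(data)}")
    sd = data.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    corr = data.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def screen_collinear(
    matrix: pd.DataFrame,
    threshold: float = 0.90,
    conserve_hub: bool = True,
) -> CorrelationScreen:
    """Greedy |r|-threshold elimination.

    ``conserve_hub=True`` keeps, from each worst pair, the variable with more
    high-correlation partners; ``False`` flips the rule (drops the hub).
    Deterministic given column order; tie-broken steps are flagged in the log.
    """
    cols = list(matrix.columns)
    absm = matrix.abs().to_numpy(dtype=float).copy()
    np.fill_diagonal(absm, 0.0)
    order = {c: i for i, c in enumerate(cols)}
    retained = list(cols)
    rows: list[dict] = []
    step = 0
    while True:
        idx = [order[c] for c in retained]
        sub = absm[np.ix_(idx, idx)]
        if sub.size == 0 or sub.max() <= threshold:
            break
        step += 1
        # worst pair; scan order breaks exact ties deterministically
        i_loc, j_loc = divmod(int(sub.argmax()), sub.shape[1])
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        a, b = retained[i_loc], retained[j_loc]
        r_ab = float(matrix.loc[a, b])

        def high_count(v: str) -> int:
            return int(
                sum(
                    1
                    for u in retained
                    if u != v and absm[order[v], order[u]] > threshold
                )
            )

        def abs_sum(v: str) -> float:
            return float(sum(absm[order[v], order[u]] for u in retained if u != v))

        ca, cb = high_count(a), high_count(b)
        tie_count = ca == cb
        tie_sum = False
        if ca != cb:
            keep = a if (ca > cb) == conserve_hub else b
        else:
            sa, sb = abs_sum(a), abs_sum(b)
            if not np.isclose(sa, sb):
                keep = a if (sa > sb) == conserve_hub else b
            else:
                tie_sum = True
                keep = a  # earlier input column wins
        drop = b if keep == a else a
        retained.remove(drop)
        rows.append(
            {
                "step": step,
                "var_a": a,
                "var_b": b,
                "r": r_ab,
                "conserved": keep,
                "eliminated": drop,
                "count_a": ca,
                "count_b": cb,
                "tie_count": tie_count,
                "tie_sum": tie_sum,
            }
        )
    log = pd.DataFrame(
        rows,
        columns=[
            "step", "var_a", "var_b", "r", "conserved", "eliminated",
            "count_a", "count_b", "tie_count", "tie_sum",
        ],
    )
    eliminated = [c for c in cols if c not in retained]
    return CorrelationScreen(
        variables=cols,
        matrix=matrix,
        threshold=threshold,
        retained=retained,
        eliminated=eliminated,
        log=log,
    )
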
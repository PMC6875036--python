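"""Horizontal-transfer inference by element-vs-host distance comparison.

Under vertical transmission an element evolves neutrally (at least as fast
as a host gene under purifying selection), so between two species the
element distance is expected to be at least the orthologous host-gene
distance. A species pair whose element distance falls strictly below its
host distance therefore supports horizontal transfer; no additional
significance test is applied — the per-pair inequality and its aggregate
count are the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = ["HTComparison", "PairResult", "ht_compare", "ht_report"]


@dataclass
class PairResult:
    species_a: str
    species_b: str
    d_te: float
    d_host: float

    @property
    def te_lower(self) -> bool:
        return self.d_te < self.d_host


def _summary(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        return {"mean": math.nan, "sd": math.nan,
                "min": math.nan, "max": math.nan}
    return {"mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
            "min": float(values.min()), "max": float(values.max())}


@dataclass
class HTComparison:
    pairs: list[PairResult]
    te_summary: dict[str, float] = field(default_factory=dict)
    host_summary: dict[str, float] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_te_lower(self) -> int:
        return sum(p.te_lower for p in self.pairs)


def ht_compare(te_dm: DistanceMatrix, host_dm: DistanceMatrix,
               pair_scheme: str = "all",
               groups: Optional[dict[str, str]] = None) -> HTComparison:
    """Compare element and host distances over species pairs.

    Pairs are formed among the taxa shared by both matrices: all pairs, or
    (``pair_scheme="within_groups"``) only pairs within each group of the
    ``groups`` map — e.g. two groups of 4 and 20 species give 6 + 190 =
    196 comparisons. Pairs with an undefined distance on either side are
    dropped with a warning; ties count against transfer.
    """
    shared = [t for t in te_dm.taxa if t in set(host_dm.taxa)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared taxa between matrices")
    if pair_scheme == "within_groups":
        if groups is None:
            raise ValueError("within_groups scheme requires a groups map")
        shared = [t for t in shared if t in groups]
    pairs: list[PairResult] = []
    for i, a in enumerate(shared):
        for b in shared[i + 1:]:
            if pair_scheme == "within_groups" and groups[a] != groups[b]:
                continue
            d_te = te_dm.value(a, b)
            d_host = host_dm.value(a, b)
            if math.isnan(d_te) or math.isnan(d_host):
                warnings.warn(f"pair ({a}, {b}) dropped: undefined distance")
                continue
            pairs.append(PairResult(a, b, d_te, d_host))
    te_vals = np.array([p.d_te for p in pairs])
    host_vals = np.array([p.d_host for p in pairs])
    return HTComparison(pairs=pairs, te_summary=_summary(te_vals),
                        host_summary=_summary(host_vals))


def ht_report(cmp: HTComparison, path: Optional[str | Path] = None
              ) -> tuple[pd.DataFrame, str]:
    """Per-pair table plus a text summary.

    Summary lines follow the "average X; SD ± Y; range Zmin–Zmax"
    convention of distance-comparison reporting."""
    df = pd.DataFrame(
        [(p.species_a, p.species_b, p.d_te, p.d_host, p.te_lower)
         for p in cmp.pairs],
        columns=["species_a", "species_b", "d_te", "d_host", "te_lower"])

    def line(name: str, s: dict[str, float]) -> str:
        if cmp.n_pairs == 0:
            return f"{name}: no defined pairs"
        return (f"{name}: average {s['mean']:.3f}; SD ± {s['sd']:.3f}; "
                f"range {s['min']:.3f}–{s['max']:.3f}")

    text = "\n".join([
        f"pairs compared: {cmp.n_pairs}",
        f"pairs with element distance below host distance: "
        f"{cmp.n_te_lower}/{cmp.n_pairs}",
        line("element distances", cmp.te_summary),
        line("host distances", cmp.host_summary),
    ])
    if path is not None:
        path = Path(path)
        df.to_csv(path, sep="\t", index=False)
        path.with_suffix(".summary.txt").write_text(text + "\n")
    return df, text
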
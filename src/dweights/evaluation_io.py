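"""Model-comparison layer and file I/O.

Implements the evaluation toolkit for comparing disability-weight sets --
Pearson correlation against a reference set, decile-bin severity
distributions, best/worst-state extremes, and the utility comparison
``1 - dw`` vs externally supplied utilities -- plus CSV schemas for every
record type in the pipeline and the packaged reference table.

The packaged fixture (``data/kr_dw_2014_reference.csv``) transcribes the
published disability weights for 256 health states valued by the 2014 South
Korean general-population surveys under all four models, alongside the GBD
2010 reference weights for the 220 overlapping states.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pc_model import DWEstimate, estimates_to_frame
from .survey_sim import (
    PHE_LADDER,
    PCResponse,
    PHERecord,
    SGRecord,
    SimConfig,
    StateRegistry,
    VASResponse,
)

__all__ = [
    "BinDistribution",
    "MalformedRowError",
    "UndefinedCorrelationError",
    "load_reference_table",
    "pearson",
    "bin_distribution",
    "compare_vs_utilities",
    "extremes_report",
    "write_pc_csv",
    "read_pc_csv",
    "write_vas_csv",
    "read_vas_csv",
    "write_sg_csv",
    "read_sg_csv",
    "write_phe_csv",
    "read_phe_csv",
    "write_estimates_csv",
    "read_estimates_csv",
    "write_manifest",
]

REFERENCE_RESOURCE = "kr_dw_2014_reference.csv"
MODEL_COLUMNS = ("model1", "model2", "model3", "model4")


class UndefinedCorrelationError(ValueError):
    """Correlation requested on a zero-variance vector."""


class MalformedRowError(ValueError):
    """A CSV row violating the record schema, reported with its line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


# ---------------------------------------------------------------------------
# Reference fixture
# ---------------------------------------------------------------------------

def load_reference_table() -> pd.DataFrame:
    """Load the packaged reference table of published disability weights.

    Columns: ``state_id``, ``label``, ``gbd2010`` (NaN for the 36 states not
    in the GBD 2010 set), ``model1`` .. ``model4``.  Shape and column
    contents are validated on load.
    """
    with resources.files("dweights.data").joinpath(REFERENCE_RESOURCE).open("rb") as fh:
        raw = fh.read()
    df = pd.read_csv(pd.io.common.BytesIO(raw))
    if len(df) != 256:
        raise ValueError(f"reference table must have 256 rows, found {len(df)}")
    if int(df["gbd2010"].notna().sum()) != 220:
        raise ValueError("reference table must carry 220 GBD 2010 values")
    for c in MODEL_COLUMNS:
        if df[c].isna().any():
            raise ValueError(f"reference column {c} has missing values")
    df.attrs["sha256"] = hashlib.sha256(raw).hexdigest()
    return df


# ---------------------------------------------------------------------------
# Comparison statistics
# ---------------------------------------------------------------------------

def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Pearson correlation with pairwise deletion of missing values.

    Returns ``(r, n_used)``; raises on fewer than 3 complete pairs or a
    zero-variance input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be paired (equal length)")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r = stats.pearsonr(x, y).statistic
    return float(r), int(len(x))


@dataclass(frozen=True)
class BinDistribution:
    """Decile-bin histogram of a disability-weight vector.

    Bins are half-open ``[lo, hi)`` with the final bin closed at 1.0;
    values outside [0, 1] land in ``n_overflow`` with a warning.
    """

    edges: tuple[float, ...]
    counts: tuple[int, ...]
    n_overflow: int

    @property
    def n(self) -> int:
        return sum(self.counts) + self.n_overflow

    @property
    def percentages(self) -> tuple[float, ...]:
        total = sum(self.counts) + self.n_overflow
        return tuple(round(100.0 * c / total, 1) for c in self.counts)

    def proportion_below(self, cut: float) -> float:
        """Share of binned values in bins entirely below ``cut`` (in %)."""
        if cut not in self.edges:
            raise ValueError(f"{cut} is not a bin edge")
        upto = self.edges.index(cut)
        return 100.0 * sum(self.counts[:upto]) / self.n

    def to_frame(self) -> pd.DataFrame:
        labels = [
            f"{lo:.1f}-{hi:.1f}" for lo, hi in zip(self.edges[:-1], self.edges[1:])
        ]
        return pd.DataFrame(
            {"bin": labels, "n": self.counts, "pct": self.percentages}
        )


def bin_distribution(
    dws: Sequence[float],
    edges: Sequence[float] | None = None,
) -> BinDistribution:
    """Histogram a weight vector into the standard 0.1-wide severity bins."""
    dws = np.asarray(dws, dtype=float)
    dws = dws[~np.isnan(dws)]
    if dws.size == 0:
        raise ValueError("empty weight vector")
    if edges is None:
        edges = np.round(np.linspace(0.0, 1.0, 11), 10)
    edges = np.asarray(edges, dtype=float)
    inside = (dws >= edges[0]) & (dws <= edges[-1])
    n_overflow = int((~inside).sum())
    if n_overflow:
        warnings.warn(
            f"{n_overflow} weight(s) outside [{edges[0]}, {edges[-1]}] counted "
            "in the overflow bucket",
            RuntimeWarning,
            stacklevel=2,
        )
    counts, _ = np.histogram(dws[inside], bins=edges)
    return BinDistribution(tuple(edges), tuple(int(c) for c in counts), n_overflow)


def compare_vs_utilities(
    dws: Mapping[str, float],
    utilities: Mapping[str, float],
) -> tuple[float, pd.DataFrame]:
    """Correlate ``1 - dw`` with externally supplied utilities.

    Returns Pearson r over the common states and the paired scatter table
    (state_id, one_minus_dw, utility).
    """
    common = sorted(set(dws) & set(utilities))
    if len(common) < 3:
        raise ValueError(f"need >= 3 common states, got {len(common)}")
    table = pd.DataFrame(
        {
            "state_id": common,
            "one_minus_dw": [1.0 - dws[s] for s in common],
            "utility": [utilities[s] for s in common],
        }
    )
    r, _ = pearson(table["one_minus_dw"], table["utility"])
    return r, table


def extremes_report(dws: Mapping[str, float]) -> dict:
    """Highest- and lowest-weight states with ties reported as sets."""
    if not dws:
        raise ValueError("empty weight map")
    s = pd.Series(dws, dtype=float).dropna()
    hi, lo = float(s.max()), float(s.min())
    ranked = s.sort_values(ascending=False)
    return {
        "max_dw": hi,
        "max_states": sorted(s.index[s == hi]),
        "min_dw": lo,
        "min_states": sorted(s.index[s == lo]),
        "ranking": ranked,
    }


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

def _read_checked(path, expected_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != expected_cols:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match schema {expected_cols}"
        )
    return df


def write_pc_csv(pc: Sequence[PCResponse], path) -> None:
    pd.DataFrame(
        [(r.respondent_id, r.state_a, r.state_b, int(r.chose_a_healthier)) for r in pc],
        columns=["respondent_id", "state_a", "state_b", "chose_a_healthier"],
    ).to_csv(path, index=False)


def read_pc_csv(path) -> list[PCResponse]:
    df = _read_checked(path, ["respondent_id", "state_a", "state_b", "chose_a_healthier"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                PCResponse(row.respondent_id, row.state_a, row.state_b,
                           bool(int(row.chose_a_healthier)))
            )
        except ValueError as e:
            raise MalformedRowError(i, str(e)) from e
    return out


def write_vas_csv(vas: Sequence[VASResponse], path) -> None:
    pd.DataFrame(
        [(r.respondent_id, r.state_id, r.value) for r in vas],
        columns=["respondent_id", "state_id", "value"],
    ).to_csv(path, index=False)


def read_vas_csv(path) -> list[VASResponse]:
    df = _read_checked(path, ["respondent_id", "state_id", "value"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(VASResponse(row.respondent_id, row.state_id, float(row.value)))
        except ValueError as e:
            raise MalformedRowError(i, str(e)) from e
    return out


def write_sg_csv(sg: Sequence[SGRecord], path) -> None:
    pd.DataFrame(
        [
            (r.respondent_id, r.state_id, int(r.worse_than_dead),
             "" if r.endpoint_p is None else f"{r.endpoint_p:.2f}")
            for r in sg
        ],
        columns=["respondent_id", "state_id", "worse_than_dead", "endpoint_p"],
    ).to_csv(path, index=False)


def read_sg_csv(path) -> list[SGRecord]:
    df = _read_checked(path, ["respondent_id", "state_id", "worse_than_dead", "endpoint_p"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            p = None if row.endpoint_p == "" else float(row.endpoint_p)
            out.append(SGRecord(row.respondent_id, row.state_id,
                                bool(int(row.worse_than_dead)), p))
        except ValueError as e:
            raise MalformedRowError(i, str(e)) from e
    return out


def _serialize_trace(trace) -> str:
    return ";".join(f"{x}:{'B' if b else 'A'}" for x, b in trace)


def _parse_trace(s: str):
    if not s:
        return ()
    out = []
    for tok in s.split(";"):
        x, c = tok.split(":")
        out.append((int(x), c == "B"))
    return tuple(out)


def _serialize_bracket(bracket) -> str:
    lo, hi = bracket
    return f"{'' if lo is None else lo}~{'' if hi is None else hi}"


def _parse_bracket(s: str):
    lo, hi = s.split("~")
    return (None if lo == "" else int(lo), None if hi == "" else int(hi))


def write_phe_csv(phe: Sequence[PHERecord], path) -> None:
    pd.DataFrame(
        [
            (r.respondent_id, r.state_id, _serialize_trace(r.trace),
             _serialize_bracket(r.final_bracket))
            for r in phe
        ],
        columns=["respondent_id", "state_id", "trace", "final_bracket"],
    ).to_csv(path, index=False)


def read_phe_csv(path) -> list[PHERecord]:
    df = _read_checked(path, ["respondent_id", "state_id", "trace", "final_bracket"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                PHERecord(row.respondent_id, row.state_id,
                          _parse_trace(row.trace), _parse_bracket(row.final_bracket))
            )
        except ValueError as e:
            raise MalformedRowError(i, str(e)) from e
    return out


def write_estimates_csv(estimates: Sequence[DWEstimate], path) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False, float_format="%.6f")


def read_estimates_csv(path) -> list[DWEstimate]:
    df = _read_checked(path, ["state_id", "dw", "ci_lo", "ci_hi", "model_tag"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                DWEstimate(row.state_id, float(row.dw),
                           float(row.ci_lo) if row.ci_lo != "" else float("nan"),
                           float(row.ci_hi) if row.ci_hi != "" else float("nan"),
                           row.model_tag)
            )
        except ValueError as e:
            raise MalformedRowError(i, str(e)) from e
    return out


def write_manifest(config: SimConfig, registry: StateRegistry, path) -> None:
    """Record the simulation conditions next to the emitted response files."""
    manifest = {
        "seed": config.seed,
        "n_respondents": config.n_respondents,
        "k_pairs": config.k_pairs,
        "sigma_pc": config.sigma_pc,
        "sigma_vas": config.sigma_vas,
        "sigma_sg": config.sigma_sg,
        "sigma_phe": config.sigma_phe,
        "n_states": len(registry),
        "n_substantive": len(registry.substantive_ids),
        "phe_ladder": list(PHE_LADDER),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
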
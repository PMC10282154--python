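"""Instrument selection: p-value filtering, greedy LD clumping, F statistics.

Clumping here consumes an explicit matrix of squared LD correlations
(:class:`LDPanel`) rather than reference genotypes, which keeps the procedure
deterministic and testable at desk scale.  The greedy rule is the usual one:
repeatedly promote the most significant remaining variant to index status and
discard every remaining variant on the same chromosome within the window whose
r² with it exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .summary_data import AnalysisError, SummaryStats

__all__ = ["LDPanel", "InstrumentSet", "select_by_pvalue", "ld_clump",
           "f_statistics", "WEAK_F_THRESHOLD"]

#: Conventional weak-instrument flag: mean F below this (strictly) is weak.
WEAK_F_THRESHOLD = 10.0


@dataclass
class LDPanel:
    """Squared LD correlations between a set of variants.

    ``r2`` is symmetric with a unit diagonal and entries in [0, 1]; rows and
    columns follow ``variant_ids``.
    """

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValueError(f"r2 must be {n}x{n}, got {self.r2.shape}")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._index[a], self._index[b]])
        except KeyError as err:
            raise AnalysisError(f"variant {err.args[0]!r} absent from LD panel") from None

    @classmethod
    def from_tsv(cls, path) -> "LDPanel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids,
                     columns=self.variant_ids).to_csv(path, sep="\t")


@dataclass
class InstrumentSet:
    """Index variants surviving clumping, with their strength statistics."""

    variant_ids: list[str]
    per_snp_F: np.ndarray
    mean_F: float
    p_threshold: float

    @property
    def weak(self) -> bool:
        return self.mean_F < WEAK_F_THRESHOLD

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.variant_ids) + "\n")


def select_by_pvalue(stats: SummaryStats, threshold: float = 5e-6) -> SummaryStats:
    """Variants with p below the instrument threshold, original order kept.

    The genome-wide 5e-8 convention is relaxed to 5e-6 by default to improve
    instrument power for weakly heritable behavioural exposures.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    keep = stats.table["pval"] < threshold
    if not keep.any():
        warnings.warn(
            f"{stats.trait_name}: no variants pass p < {threshold:g}")
    return SummaryStats(stats.trait_name, stats.trait_type,
                        stats.table.loc[keep].reset_index(drop=True))


def ld_clump(stats: SummaryStats, panel: LDPanel, window_bp: int = 1_000_000,
             r2_max: float = 0.001, p_threshold: float = np.nan) -> InstrumentSet:
    """Greedy p-value-ordered LD clumping against an explicit r² panel.

    Ties on p are broken lexicographically by variant id, so the result does
    not depend on input row order.  Cross-chromosome pairs are never pruned.
    """
    tbl = stats.table
    missing = [v for v in tbl["variant_id"] if v not in panel._index]
    if missing:
        raise AnalysisError(f"variant {missing[0]!r} absent from LD panel")

    order = tbl.sort_values(["pval", "variant_id"], kind="mergesort")
    remaining = {r.variant_id: r for r in order.itertuples(index=False)}
    kept: list = []
    for vid in list(remaining):
        if vid not in remaining:
            continue
        row = remaining.pop(vid)
        kept.append(row)
        for other_id in list(remaining):
            o = remaining[other_id]
            if str(o.chrom) != str(row.chrom):
                continue
            if abs(int(o.pos) - int(row.pos)) > window_bp:
                continue
            if panel.lookup(vid, other_id) > r2_max:
                del remaining[other_id]

    kept_ids = {r.variant_id for r in kept}
    in_order = tbl.loc[tbl["variant_id"].isin(kept_ids)]
    F = (in_order["beta"] / in_order["se"]).to_numpy() ** 2
    return InstrumentSet(list(in_order["variant_id"]), F,
                         float(F.mean()) if len(F) else float("nan"),
                         p_threshold)


def f_statistics(instruments) -> tuple[np.ndarray, float, bool]:
    """Per-SNP and mean F statistics from a harmonized set.

    Uses the summary-data approximation F_j = (beta_xj / se_xj)²; the
    relevance assumption is flagged as questionable when mean F < 10
    (strictly).
    """
    bx = np.asarray(instruments.bx, dtype=float)
    sx = np.asarray(instruments.sx, dtype=float)
    if bx.size == 0:
        raise AnalysisError("F statistics need a non-empty instrument set")
    per_snp = (bx / sx) ** 2
    mean_F = float(per_snp.mean())
    return per_snp, mean_F, mean_F < WEAK_F_THRESHOLD
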
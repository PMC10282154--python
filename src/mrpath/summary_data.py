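"""GWAS summary-statistics containers, I/O and allele harmonization.

Summary statistics for one trait are held as a :class:`SummaryStats` — a thin
wrapper around a pandas DataFrame with one row per variant.  Two traits are
joined into a :class:`HarmonizedSet`, in which every retained variant's outcome
association is expressed per copy of the *exposure's* effect allele.  That
alignment is what every downstream MR estimator assumes.

Harmonization follows the standard two-sample MR conventions:

* alleles matching exactly are kept as-is;
* swapped alleles flip the outcome beta's sign (and reflect the allele
  frequency);
* alleles matching only after strand complement are complemented first and
  then treated the same way;
* palindromic variants (A/T or C/G) cannot be resolved from allele labels, so
  they are oriented by effect-allele frequency when both studies' frequencies
  are clearly away from 0.5, and dropped as ambiguous otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationRecord",
    "SummaryStats",
    "HarmonizedSet",
    "read_summary_stats",
    "harmonize",
    "DEFAULT_COLUMNS",
    "AnalysisError",
    "FormatError",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default header names of a summary-statistics file, in canonical order.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_CANONICAL = list(DEFAULT_COLUMNS)


class AnalysisError(RuntimeError):
    """An MR analysis step could not proceed (empty overlap, too few SNPs...)."""


class FormatError(ValueError):
    """An input file does not conform to the expected layout."""


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's estimated association with one trait.

    ``beta`` is on the log-odds scale for binary traits and in trait units (or
    SD) for continuous ones; ``se`` is its standard error.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be positive")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: alleles must differ")


@dataclass
class SummaryStats:
    """All per-variant associations of a single GWAS.

    The ``table`` DataFrame uses the canonical column names
    (``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
    pval, n``) and is unique by ``variant_id``.
    """

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in _CANONICAL if c not in self.table.columns]
        if missing:
            raise FormatError(f"summary table missing columns: {missing}")
        if self.table["variant_id"].duplicated().any():
            dupes = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant ids: {sorted(set(dupes))[:5]}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> list[AssociationRecord]:
        return [
            AssociationRecord(
                variant_id=r.variant_id, chrom=str(r.chrom), pos=int(r.pos),
                effect_allele=r.effect_allele, other_allele=r.other_allele,
                eaf=None if pd.isna(r.eaf) else float(r.eaf),
                beta=float(r.beta), se=float(r.se), pval=float(r.pval), n=int(r.n),
            )
            for r in self.table.itertuples(index=False)
        ]

    def subset(self, variant_ids: Sequence[str]) -> "SummaryStats":
        """Rows for the given variants, preserving this study's row order."""
        keep = self.table["variant_id"].isin(set(variant_ids))
        return SummaryStats(self.trait_name, self.trait_type,
                            self.table.loc[keep].reset_index(drop=True))

    def to_tsv(self, path, column_map: Mapping[str, str] = DEFAULT_COLUMNS) -> None:
        out = self.table.rename(columns=dict(column_map))
        out.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure and outcome associations aligned to a common effect allele.

    ``bx, sx`` are the exposure betas/SEs and ``by, sy`` the outcome ones, all
    per copy of the exposure's effect allele.  ``dropped`` lists the variants
    from the id intersection that could not be aligned, with a reason.
    """

    exposure_name: str
    outcome_name: str
    variants: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.bx = np.asarray(self.bx, dtype=float)
        self.sx = np.asarray(self.sx, dtype=float)
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        n = len(self.variants)
        if not (len(self.bx) == len(self.sx) == len(self.by) == len(self.sy) == n):
            raise ValueError("harmonized vectors must share one length")

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    def subset(self, keep: Sequence[int] | Sequence[bool]) -> "HarmonizedSet":
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(int)  # empty selections arrive as float64
        return HarmonizedSet(
            self.exposure_name, self.outcome_name,
            [self.variants[i] for i in idx],
            self.bx[idx], self.sx[idx], self.by[idx], self.sy[idx],
            dropped=list(self.dropped),
        )

    def without(self, variant_ids: Sequence[str]) -> "HarmonizedSet":
        drop = set(variant_ids)
        return self.subset([i for i, v in enumerate(self.variants) if v not in drop])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variant_id": self.variants, "bx": self.bx,
                             "sx": self.sx, "by": self.by, "sy": self.sy})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_summary_stats(path, trait_type: str, trait_name: str | None = None,
                       column_map: Mapping[str, str] | None = None,
                       sep: str | None = None) -> SummaryStats:
    """Read a delimited summary-statistics file.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    trait_type
        ``"binary"`` or ``"continuous"``.
    column_map
        Maps canonical field names to the file's header names; defaults to
        ``DEFAULT_COLUMNS`` (SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N).
    sep
        Field separator; sniffed from the header line when omitted.

    Rows with a non-positive SE or a missing beta are dropped; the count is
    recorded on the returned object as ``n_dropped``.  Alleles are upper-cased.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        if not header.strip():
            raise FormatError(f"{path}: empty file")
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[_CANONICAL]

    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    bad = df["se"].isna() | (df["se"] <= 0) | df["beta"].isna()
    n_dropped = int(bad.sum())
    df = df.loc[~bad].reset_index(drop=True)
    return SummaryStats(trait_name or str(path), trait_type, df, n_dropped=n_dropped)


def pvalue_consistency(stats: SummaryStats, rtol: float = 0.1) -> np.ndarray:
    """Check each record's p-value against its two-sided normal Wald test.

    Returns a boolean mask (True = consistent).  Consistency is judged on the
    z-score scale — the |beta/se| statistic versus the z implied by the
    reported p — within relative tolerance ``rtol``, which tolerates the
    rounding real summary files carry.  Rows with p at the float boundaries
    are treated as consistent.
    """
    from scipy.stats import norm
    z_obs = np.abs(stats.table["beta"] / stats.table["se"]).to_numpy()
    p = stats.table["pval"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        z_imp = norm.isf(np.clip(p, 0.0, 1.0) / 2)
    ok = np.isclose(z_obs, z_imp, rtol=rtol, atol=0.05)
    ok |= ~np.isfinite(z_imp)
    return ok


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _freq_side_clear(eaf: float | None, window: float) -> bool:
    return eaf is not None and not np.isnan(eaf) and abs(eaf - 0.5) > window


def harmonize(exposure: SummaryStats, outcome: SummaryStats,
              palindromic_eaf_window: float = 0.08) -> HarmonizedSet:
    """Align outcome associations to the exposure's effect alleles.

    Variants are matched by id.  Palindromic variants are oriented by
    effect-allele frequency only when both studies' frequencies are outside
    ``[0.5 - window, 0.5 + window]``; otherwise they are dropped with reason
    ``"palindromic_ambiguous"``.  Unresolvable allele pairs are dropped with
    reason ``"allele_mismatch"``.
    """
    ex = exposure.table.set_index("variant_id")
    ot = outcome.table.set_index("variant_id")
    shared = [v for v in exposure.table["variant_id"] if v in ot.index]
    if not shared:
        raise AnalysisError(
            f"no shared variants between {exposure.trait_name!r} and {outcome.trait_name!r}")

    variants, bx, sx, by, sy, dropped = [], [], [], [], [], []
    w = palindromic_eaf_window
    for v in shared:
        e, o = ex.loc[v], ot.loc[v]
        ea, oa = e.effect_allele, e.other_allele
        o_ea, o_oa = o.effect_allele, o.other_allele
        e_eaf = None if pd.isna(e.eaf) else float(e.eaf)
        o_eaf = None if pd.isna(o.eaf) else float(o.eaf)
        beta_y, flip = float(o.beta), None

        if _is_palindromic(ea, oa):
            # strand is unresolvable from labels; identity and complement-swap
            # are indistinguishable, so orient by allele frequency alone
            if {o_ea, o_oa} != {ea, oa}:
                dropped.append((v, "allele_mismatch"))
                continue
            if not (_freq_side_clear(e_eaf, w) and _freq_side_clear(o_eaf, w)):
                dropped.append((v, "palindromic_ambiguous"))
                continue
            o_eaf_aligned = o_eaf if o_ea == ea else 1.0 - o_eaf
            same_side = (e_eaf > 0.5) == (o_eaf_aligned > 0.5)
            if o_ea == ea:
                flip = not same_side
            else:
                flip = same_side
        elif (o_ea, o_oa) == (ea, oa):
            flip = False
        elif (o_ea, o_oa) == (oa, ea):
            flip = True
        else:
            c_ea = _COMPLEMENT.get(o_ea, "?")
            c_oa = _COMPLEMENT.get(o_oa, "?")
            if (c_ea, c_oa) == (ea, oa):
                flip = False
            elif (c_ea, c_oa) == (oa, ea):
                flip = True
            else:
                dropped.append((v, "allele_mismatch"))
                continue

        if flip:
            beta_y = -beta_y
        variants.append(v)
        bx.append(float(e.beta))
        sx.append(float(e.se))
        by.append(beta_y)
        sy.append(float(o.se))

    if not variants:
        warnings.warn(
            f"harmonize({exposure.trait_name}, {outcome.trait_name}): "
            "all shared variants dropped")
    return HarmonizedSet(exposure.trait_name, outcome.trait_name,
                         variants, bx, sx, by, sy, dropped=dropped)
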
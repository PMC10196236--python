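"""Genotype-level combination of binding and mutant exposure.

A patient's class I genotype is coded as an ordered 6-bit pattern
(A1,A2,B1,B2,C1,C2): a bit is 1 only when the peptide binds that allele at
the Zscale threshold AND the mutant residue protrudes in a T cell exposed
position.  DRB1 class II alleles get the analogous 2-bit pattern.  On top of
the bitmaps sit binding-change classes (Lost/Gained/Retained), the 6x5
allele-by-register minimum matrix, the Table-1-style down-selection cascade,
exposure fractions, Shannon pattern diversity, and cumulative binding
curves by reference pentamer frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

CLASS_I_SLOTS = ("A1", "A2", "B1", "B2", "C1", "C2")
CLASS_II_SLOTS = ("DRB1_1", "DRB1_2")

DEFAULT_THRESHOLD = -1.0

ChangeLabel = Literal["Lost", "Gained", "Retained"]


@dataclass(frozen=True)
class Genotype:
    case_id: str
    class_i: tuple[str, str, str, str, str, str]  # A1,A2,B1,B2,C1,C2 in input order
    class_ii: tuple[str, str]  # DRB1_1, DRB1_2

    def __post_init__(self):
        if len(self.class_i) != 6 or len(self.class_ii) != 2:
            raise ValueError("genotype needs 6 class I and 2 class II slots")

    @property
    def alleles(self) -> dict[str, str]:
        out = dict(zip(CLASS_I_SLOTS, self.class_i))
        out.update(zip(CLASS_II_SLOTS, self.class_ii))
        return out


def genotype_from_row(row) -> Genotype:
    """Build a Genotype from a genotype-table row (slot order = input order)."""
    return Genotype(
        case_id=row["case_id"],
        class_i=tuple(row[s] for s in CLASS_I_SLOTS),
        class_ii=tuple(row[s] for s in CLASS_II_SLOTS),
    )


def _bitmap(zscores: Sequence[float], exposed: bool, threshold: float, arity: int) -> str:
    z = np.asarray(zscores, dtype=float)
    if z.shape != (arity,):
        raise ValueError(f"expected {arity} zscores, got shape {z.shape}")
    if not np.isfinite(z).all():
        raise ValueError("zscores must be finite")
    if not exposed:
        return "0" * arity
    return "".join("1" if v <= threshold else "0" for v in z)


def bitmap_class_i(
    zscores: Sequence[float], exposed: bool, threshold: float = DEFAULT_THRESHOLD
) -> str:
    """6-bit A1,A2,B1,B2,C1,C2 pattern: bit=1 iff z <= threshold and exposed."""
    return _bitmap(zscores, exposed, threshold, 6)


def bitmap_class_ii(
    zscores: Sequence[float], exposed: bool, threshold: float = DEFAULT_THRESHOLD
) -> str:
    """2-bit DRB1_1,DRB1_2 analogue of :func:`bitmap_class_i`."""
    return _bitmap(zscores, exposed, threshold, 2)


def classify_binding_change(
    wt_z: float, mut_z: float, threshold: float = DEFAULT_THRESHOLD
) -> ChangeLabel:
    """Lost: bound before, not after; Gained: the reverse; else Retained."""
    if not (math.isfinite(wt_z) and math.isfinite(mut_z)):
        raise ValueError("zscores must be finite")
    wt_bound, mut_bound = wt_z <= threshold, mut_z <= threshold
    if wt_bound and not mut_bound:
        return "Lost"
    if mut_bound and not wt_bound:
        return "Gained"
    return "Retained"


@dataclass
class RegisterMatrix:
    """6 class I alleles x 5 TCEM-exposing registers of mutant zscores."""

    values: np.ndarray  # (6, 5), NaN = register undefined (e.g. near a terminus)
    min_value: float
    argmin: list[tuple[str, int]]  # (allele slot, register index 1..5)
    dominant: tuple[str, int]


def register_matrix(values: np.ndarray, tol: float = 1e-9) -> RegisterMatrix:
    """Minimum Zscale over the defined cells; ties within tol all listed.

    The dominant cell is the first tie in (A1,A2,B1,B2,C1,C2) x ascending
    register order.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (6, 5):
        raise ValueError(f"expected a 6x5 matrix, got {values.shape}")
    defined = np.isfinite(values)
    if not defined.any():
        raise ValueError("no defined (allele, register) cells")
    min_value = float(np.nanmin(values))
    argmin = [
        (CLASS_I_SLOTS[i], j + 1)
        for i in range(6)
        for j in range(5)
        if defined[i, j] and values[i, j] <= min_value + tol
    ]
    return RegisterMatrix(values, min_value, argmin, argmin[0])


@dataclass
class DownselectTable:
    """Per-case tallies of the nested down-selection cascade."""

    case_id: str
    n_mutations: int
    n_peptides_9_15: int
    n_9mers: int
    n_nonbinding_9mers: int
    n_nonbinding_or_nonTCEM: int
    n_binding: int
    n_binding_and_TCEM_exposed: int
    n_binding_TCEM_I_and_II: int

    def validate(self) -> None:
        assert self.n_nonbinding_9mers + self.n_binding == self.n_9mers
        assert (
            self.n_binding_TCEM_I_and_II
            <= self.n_binding_and_TCEM_exposed
            <= self.n_binding
            <= self.n_9mers
        )
        assert self.n_nonbinding_or_nonTCEM == self.n_9mers - self.n_binding_and_TCEM_exposed

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "n_mutations": self.n_mutations,
            "n_peptides_9_15": self.n_peptides_9_15,
            "n_9mers": self.n_9mers,
            "n_nonbinding_9mers": self.n_nonbinding_9mers,
            "n_nonbinding_or_nonTCEM": self.n_nonbinding_or_nonTCEM,
            "n_binding": self.n_binding,
            "n_binding_and_TCEM_exposed": self.n_binding_and_TCEM_exposed,
            "n_binding_TCEM_I_and_II": self.n_binding_TCEM_I_and_II,
        }


MUTATION_KEY = ["protein_id", "position", "alt_aa"]


def _z_cols(df: pd.DataFrame, slots: Sequence[str]) -> list[str]:
    cols = [f"z_mut_{s}" for s in slots]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing allele predictions: {missing}")
    return cols


def _binds_any(df: pd.DataFrame, slots: Sequence[str], threshold: float) -> pd.Series:
    z = df[_z_cols(df, slots)]
    if z.isna().any().any():
        bad = z.columns[z.isna().any()].tolist()
        raise ValueError(f"missing allele predictions in columns {bad}")
    return (z <= threshold).any(axis=1)


def downselect(
    annotations: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    dual_class_rule: Literal["mutation", "containing"] = "mutation",
    case_id: str = "",
) -> DownselectTable:
    """Table-1-style nested tallies for one case's annotation records.

    One record per (mutation x width x register).  A 9mer is *binding* iff
    any class I allele scores at or below the threshold; *TCEM presenting*
    additionally requires the register to expose the mutant.  The dual-class
    row needs a DRB1-bound, mutant-exposing 15mer for the same mutation
    ("mutation" rule) or one whose window contains the 9mer ("containing").
    """
    df9 = annotations[annotations["width"] == 9]
    df15 = annotations[annotations["width"] == 15]
    n_9 = len(df9)
    binds9 = _binds_any(df9, CLASS_I_SLOTS, threshold) if n_9 else pd.Series(dtype=bool)
    exposed9 = df9["exposed"].astype(bool) if n_9 else pd.Series(dtype=bool)
    n_binding = int(binds9.sum())
    n_bind_exposed = int((binds9 & exposed9).sum())

    n_dual = 0
    if n_9 and len(df15):
        binds15 = _binds_any(df15, CLASS_II_SLOTS, threshold)
        ok15 = df15[binds15 & df15["exposed"].astype(bool)]
        if dual_class_rule == "mutation":
            good_keys = set(map(tuple, ok15[MUTATION_KEY].itertuples(index=False)))
            cand = df9[binds9 & exposed9]
            n_dual = int(
                sum(tuple(k) in good_keys for k in cand[MUTATION_KEY].itertuples(index=False))
            )
        elif dual_class_rule == "containing":
            cand = df9[binds9 & exposed9]
            spans = {}
            for row in ok15.itertuples(index=False):
                spans.setdefault((row.protein_id, row.position, row.alt_aa), []).append(row.start)
            for row in cand.itertuples(index=False):
                starts15 = spans.get((row.protein_id, row.position, row.alt_aa), [])
                if any(s15 <= row.start and row.start + 9 <= s15 + 15 for s15 in starts15):
                    n_dual += 1
        else:
            raise ValueError(f"unknown dual_class_rule {dual_class_rule!r}")

    table = DownselectTable(
        case_id=case_id or (annotations["case_id"].iloc[0] if len(annotations) else ""),
        n_mutations=int(annotations[MUTATION_KEY].drop_duplicates().shape[0]),
        n_peptides_9_15=int(len(annotations)),
        n_9mers=n_9,
        n_nonbinding_9mers=n_9 - n_binding,
        n_nonbinding_or_nonTCEM=n_9 - n_bind_exposed,
        n_binding=n_binding,
        n_binding_and_TCEM_exposed=n_bind_exposed,
        n_binding_TCEM_I_and_II=n_dual,
    )
    table.validate()
    return table


def exposure_fraction(
    annotations: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    denominator: Literal["events", "peptides"] = "events",
) -> float:
    """Fraction of binding events (or binding peptides) exposing the mutant.

    ``events`` counts every (9mer register, allele) pair bound at threshold;
    ``peptides`` counts each bound 9mer once.  Under register-uniform binding
    the expectation is 5/9 ~ 0.55.  Returns NaN when nothing is bound.
    """
    df9 = annotations[annotations["width"] == 9]
    if not len(df9):
        return float("nan")
    z = df9[_z_cols(df9, CLASS_I_SLOTS)].to_numpy(dtype=float)
    bound = z <= threshold
    exposed = df9["exposed"].to_numpy(dtype=bool)
    if denominator == "events":
        n_events = int(bound.sum())
        if n_events == 0:
            return float("nan")
        return float(bound[exposed].sum() / n_events)
    if denominator == "peptides":
        any_bound = bound.any(axis=1)
        if not any_bound.any():
            return float("nan")
        return float((any_bound & exposed).sum() / any_bound.sum())
    raise ValueError(f"unknown denominator {denominator!r}")


def pattern_diversity(bitmaps: Sequence[str]) -> tuple[int, float]:
    """(distinct patterns, Shannon entropy in bits) of a bitmap sample."""
    if len(bitmaps) == 0:
        raise ValueError("need at least one bitmap")
    counts = pd.Series(list(bitmaps)).value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())
    return int(len(counts)), entropy


def cumulative_fraction_by_ppf(
    annotations: pd.DataFrame,
    ppf_cap: int = 10,
    threshold: float = DEFAULT_THRESHOLD,
    ppf_col: str = "hppf_mut",
) -> pd.DataFrame:
    """Cumulative bound fraction of mutant-exposing 9mer records by hPPF.

    For each integer h in 0..cap, the fraction of all mutant-exposing records
    that are bound by >= 1 class I allele and whose mutant TCEM has reference
    count <= h.  Nondecreasing by construction; input for the Weibull growth
    fit.
    """
    df9 = annotations[(annotations["width"] == 9) & annotations["exposed"].astype(bool)]
    if not len(df9):
        raise ValueError("no mutant-exposing 9mer records")
    bound = _binds_any(df9, CLASS_I_SLOTS, threshold).to_numpy()
    ppf = df9[ppf_col].to_numpy(dtype=float)
    total = len(df9)
    hs = np.arange(0, ppf_cap + 1)
    frac = [(bound & (ppf <= h)).sum() / total for h in hs]
    return pd.DataFrame({"hppf": hs, "cumulative_fraction": frac})
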
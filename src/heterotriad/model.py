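"""Shared data model for diallel heterosis / triad expression analysis.

The study design is a 2x2 complete diallel cross: two inbred families and
their two reciprocal hybrids.  Everything downstream (phenotype statistics,
differential expression, inheritance-mode classification, qPCR validation)
is expressed in terms of these four family labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FamilyDesign",
    "PhenotypeTable",
    "ExpressionMatrix",
    "SummaryStat",
    "AnnotationMap",
    "CtTable",
    "DesignError",
    "FormatError",
]


class DesignError(ValueError):
    """Raised when family labels or cross structure are inconsistent."""


class FormatError(ValueError):
    """Raised when an input table fails validation (names the offender)."""


@dataclass(frozen=True)
class FamilyDesign:
    """A 2x2 complete diallel cross.

    Parameters
    ----------
    inbred_1, inbred_2
        Labels of the two inbred (parental) families.
    hybrid_1, hybrid_2
        Labels of the two reciprocal hybrid families.
    parent_map
        hybrid label -> (dam family, sire family).  The two hybrids must be
        reciprocal: same parent pair with dam and sire swapped.
    """

    inbred_1: str = "A"
    inbred_2: str = "D"
    hybrid_1: str = "B"
    hybrid_2: str = "C"
    parent_map: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [self.inbred_1, self.inbred_2, self.hybrid_1, self.hybrid_2]
        if len(set(labels)) != 4:
            raise DesignError(f"family labels must be distinct, got {labels}")
        pm = dict(self.parent_map) or {
            self.hybrid_1: (self.inbred_1, self.inbred_2),
            self.hybrid_2: (self.inbred_2, self.inbred_1),
        }
        if set(pm) != {self.hybrid_1, self.hybrid_2}:
            raise DesignError(f"parent_map keys must be the two hybrids, got {sorted(pm)}")
        parents = {self.inbred_1, self.inbred_2}
        for hyb, (dam, sire) in pm.items():
            if {dam, sire} != parents:
                raise DesignError(
                    f"hybrid {hyb!r} parents {{{dam!r}, {sire!r}}} must be the two inbreds"
                )
        if pm[self.hybrid_1] != tuple(reversed(pm[self.hybrid_2])):
            raise DesignError("the two hybrids must be reciprocal (dam/sire swapped)")
        object.__setattr__(self, "parent_map", pm)

    @property
    def inbreds(self) -> tuple[str, str]:
        return (self.inbred_1, self.inbred_2)

    @property
    def hybrids(self) -> tuple[str, str]:
        return (self.hybrid_1, self.hybrid_2)

    @property
    def families(self) -> tuple[str, str, str, str]:
        return (self.inbred_1, self.hybrid_1, self.hybrid_2, self.inbred_2)

    def is_hybrid(self, family: str) -> bool:
        return family in self.hybrids

    def parents_of(self, hybrid: str) -> tuple[str, str]:
        if hybrid not in self.parent_map:
            raise DesignError(f"{hybrid!r} is not a hybrid in this design")
        return tuple(self.parent_map[hybrid])

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "FamilyDesign":
        return cls(
            inbred_1=str(d.get("inbred_1", "A")),
            inbred_2=str(d.get("inbred_2", "D")),
            hybrid_1=str(d.get("hybrid_1", "B")),
            hybrid_2=str(d.get("hybrid_2", "C")),
            parent_map={k: tuple(v) for k, v in dict(d.get("parent_map", {})).items()},
        )


@dataclass
class PhenotypeTable:
    """Individual-level trait measurements keyed by family.

    ``data`` has columns ``individual_id``, ``family`` and one numeric
    column per trait (mm for shell dimensions, g for weights).
    """

    data: pd.DataFrame
    design: FamilyDesign | None = None

    def __post_init__(self) -> None:
        for col in ("individual_id", "family"):
            if col not in self.data.columns:
                raise FormatError(f"phenotype table missing required column {col!r}")
        if not self.traits:
            raise FormatError("phenotype table has no trait columns")
        if self.design is not None:
            known = set(self.design.families)
            bad = sorted(set(self.data["family"]) - known)
            if bad:
                raise FormatError(f"unknown family label(s) {bad}; expected {sorted(known)}")
        vals = self.data[self.traits]
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise FormatError("non-finite trait values in phenotype table")
        if (vals.to_numpy(dtype=float) <= 0).any():
            raise FormatError("trait values must be strictly positive")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("individual_id", "family")]

    def family_values(self, family: str, trait: str) -> np.ndarray:
        sub = self.data.loc[self.data["family"] == family, trait]
        return sub.to_numpy(dtype=float)

    def family_mean(self, family: str, trait: str) -> float:
        vals = self.family_values(family, trait)
        if vals.size == 0:
            raise FormatError(f"family {family!r} has no individuals")
        return float(vals.mean())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus sample metadata.

    ``values``: DataFrame indexed by gene id with one column per sample.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``family`` and ``replicate``.
    ``unit``: ``"count"`` (raw fragments) or ``"FPKM"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    unit: str = "FPKM"

    def __post_init__(self) -> None:
        if self.unit not in ("count", "FPKM"):
            raise FormatError(f"unit must be 'count' or 'FPKM', got {self.unit!r}")
        dup = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup:
            raise FormatError(f"duplicate gene id(s): {dup}")
        for col in ("family", "replicate"):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample metadata missing column {col!r}")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"sample(s) missing from metadata: {missing}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise FormatError("expression values must be finite and nonnegative")
        # align metadata row order to the value columns
        self.sample_meta = self.sample_meta.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def families(self) -> list[str]:
        return sorted(self.sample_meta["family"].unique())

    def samples_of(self, family: str) -> list[str]:
        sel = self.sample_meta.index[self.sample_meta["family"] == family]
        if len(sel) == 0:
            raise FormatError(f"no samples for family {family!r}")
        return list(sel)

    def family_values(self, family: str) -> pd.DataFrame:
        """Genes x replicates sub-matrix for one family."""
        return self.values[self.samples_of(family)]

    def family_mean(self, family: str) -> pd.Series:
        return self.family_values(family).mean(axis=1)


@dataclass(frozen=True)
class SummaryStat:
    """Mean +/- SD over n replicates, the unit of the summary t-test."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "SummaryStat":
        arr = np.asarray(list(values), dtype=float)
        if arr.size < 2:
            raise ValueError("need >= 2 values for a SummaryStat")
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


@dataclass
class AnnotationMap:
    """gene id -> set of term ids, with optional human-readable term names.

    Genes absent from the map are simply unannotated, never an error.
    """

    gene_to_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = sorted(g for g, t in self.gene_to_terms.items() if not t)
        if empty:
            raise FormatError(f"gene(s) with empty term sets: {empty}")

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for t in self.gene_to_terms.values():
            out |= t
        return out

    def term_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for g, terms in self.gene_to_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(g)
        return out

    def name_of(self, term: str) -> str:
        return self.term_names.get(term, term)


@dataclass
class CtTable:
    """qPCR cycle-threshold table.

    ``data`` columns: gene_id, family, replicate, ct_target, ct_reference.
    The reference gene (e.g. beta-actin) is implicit: one ct_reference per row.
    """

    data: pd.DataFrame

    REQUIRED = ("gene_id", "family", "replicate", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise FormatError(f"Ct table missing column {col!r}")
        for col in ("ct_target", "ct_reference"):
            arr = self.data[col].to_numpy(dtype=float)
            if not np.isfinite(arr).all():
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise FormatError(f"non-finite {col} at row {bad}")

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    @property
    def families(self) -> list[str]:
        return sorted(self.data["family"].unique())

    def delta_ct(self) -> pd.Series:
        """Per-replicate dCt = Ct(target) - Ct(reference)."""
        return self.data["ct_target"] - self.data["ct_reference"]
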
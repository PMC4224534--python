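"""Read, validate and transform the species-by-trait matrix and species metadata.

Six life-history traits are carried per species: longevity (yr), age at
maturity (yr), maximum body length (cm), length at maturity (cm), fecundity
(offspring per female per year) and offspring size (mm; egg diameter, egg-case
size or larval size, used interchangeably as one numeric column).  All traits
must be strictly positive so that a log10 transform is defined; ordination
operates on log10-then-z-scored columns.

Missing values are never imputed here: the input table must be complete, and
values that were estimated from related species are only *flagged* (column
``imputed``) so their share can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

#: Canonical trait column order used throughout the package.
TRAIT_NAMES: tuple[str, ...] = (
    "longevity",
    "age_maturity",
    "max_length",
    "length_maturity",
    "fecundity",
    "offspring_size",
)

TAXONOMY_RANKS: tuple[str, ...] = (
    "superclass",
    "class",
    "order",
    "family",
    "genus",
    "species_name",
)

BIOGEOGRAPHY_CLASSES = frozenset({"Arctic", "arcto-boreal", "boreal"})
HABITAT_CLASSES = frozenset({"demersal", "pelagic"})
DIET_CLASSES = frozenset(
    {
        "benthivorous",
        "planktivorous",
        "piscivorous",
        "bentho-piscivorous",
        "plankto-piscivorous",
    }
)


class TraitValidationError(ValueError):
    """Raised when a trait table or metadata table violates its contract."""


@dataclass(frozen=True)
class TraitRecord:
    """One species' life-history trait values with imputation provenance."""

    species_id: str
    longevity: float
    age_maturity: float
    max_length: float
    length_maturity: float
    fecundity: float
    offspring_size: float
    imputed_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in TRAIT_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise TraitValidationError(
                    f"species {self.species_id!r}: trait {name!r} must be a "
                    f"finite positive number (got {v!r}); log10 is undefined"
                )
        if self.length_maturity > self.max_length:
            raise TraitValidationError(
                f"species {self.species_id!r}: length_maturity "
                f"({self.length_maturity}) exceeds max_length ({self.max_length})"
            )
        if self.age_maturity > self.longevity:
            raise TraitValidationError(
                f"species {self.species_id!r}: age_maturity "
                f"({self.age_maturity}) exceeds longevity ({self.longevity})"
            )
        unknown = set(self.imputed_flags) - set(TRAIT_NAMES)
        if unknown:
            raise TraitValidationError(
                f"species {self.species_id!r}: unknown imputed trait names {sorted(unknown)}"
            )


@dataclass(frozen=True)
class SpeciesMeta:
    """Biogeography, habitat, diet and 6-rank taxonomy for one species."""

    species_id: str
    biogeography: str
    habitat: str
    diet: str
    taxonomy_path: tuple[str, str, str, str, str, str]

    def __post_init__(self) -> None:
        if self.biogeography not in BIOGEOGRAPHY_CLASSES:
            raise TraitValidationError(
                f"species {self.species_id!r}: biogeography {self.biogeography!r} "
                f"not in {sorted(BIOGEOGRAPHY_CLASSES)}"
            )
        if self.habitat not in HABITAT_CLASSES:
            raise TraitValidationError(
                f"species {self.species_id!r}: habitat {self.habitat!r} "
                f"not in {sorted(HABITAT_CLASSES)}"
            )
        if self.diet not in DIET_CLASSES:
            raise TraitValidationError(
                f"species {self.species_id!r}: diet {self.diet!r} "
                f"not in {sorted(DIET_CLASSES)}"
            )
        if len(self.taxonomy_path) != 6 or any(
            not isinstance(t, str) or not t for t in self.taxonomy_path
        ):
            raise TraitValidationError(
                f"species {self.species_id!r}: taxonomy_path must have exactly "
                f"6 non-empty levels, got {self.taxonomy_path!r}"
            )


class TraitTable:
    """Validated collection of :class:`TraitRecord` plus optional metadata.

    Internally backed by pandas DataFrames indexed by ``species_id``:
    ``traits`` (six float columns in :data:`TRAIT_NAMES` order), ``imputed``
    (boolean, same shape) and ``meta`` (may be ``None`` when no metadata
    were supplied).
    """

    def __init__(
        self,
        traits: pd.DataFrame,
        imputed: pd.DataFrame | None = None,
        meta: pd.DataFrame | None = None,
    ) -> None:
        if traits.index.has_duplicates:
            dupes = traits.index[traits.index.duplicated()].unique().tolist()
            raise TraitValidationError(f"duplicate species_id values: {dupes}")
        missing = [c for c in TRAIT_NAMES if c not in traits.columns]
        if missing:
            raise TraitValidationError(f"trait table missing columns: {missing}")
        traits = traits.loc[:, list(TRAIT_NAMES)].astype(float)
        if imputed is None:
            imputed = pd.DataFrame(
                False, index=traits.index, columns=list(TRAIT_NAMES)
            )
        imputed = imputed.loc[traits.index, list(TRAIT_NAMES)].astype(bool)
        self.traits = traits
        self.imputed = imputed
        self.meta = meta
        # record-level validation surfaces the offending species by name
        for rec in self._iter_records():
            pass
        if meta is not None:
            missing_meta = set(traits.index) - set(meta.index)
            if missing_meta:
                raise TraitValidationError(
                    f"metadata missing for species: {sorted(missing_meta)}"
                )
            for m in self.iter_meta():
                pass

    def _iter_records(self) -> Iterator[TraitRecord]:
        for sid, row in self.traits.iterrows():
            flags = frozenset(
                t for t in TRAIT_NAMES if bool(self.imputed.at[sid, t])
            )
            yield TraitRecord(species_id=str(sid), imputed_flags=flags, **row.to_dict())

    def records(self) -> list[TraitRecord]:
        return list(self._iter_records())

    def iter_meta(self) -> Iterator[SpeciesMeta]:
        if self.meta is None:
            return
        for sid in self.traits.index:
            row = self.meta.loc[sid]
            yield SpeciesMeta(
                species_id=str(sid),
                biogeography=str(row["biogeography"]),
                habitat=str(row["habitat"]),
                diet=str(row["diet"]),
                taxonomy_path=tuple(str(row[r]) for r in TAXONOMY_RANKS),
            )

    @property
    def species_ids(self) -> list[str]:
        return [str(s) for s in self.traits.index]

    def __len__(self) -> int:
        return len(self.traits)

    def subset(self, species: Iterable[str]) -> "TraitTable":
        keep = [s for s in self.species_ids if s in set(species)]
        meta = self.meta.loc[keep] if self.meta is not None else None
        return TraitTable(self.traits.loc[keep], self.imputed.loc[keep], meta)


@dataclass
class StandardizedTraitMatrix:
    """Log10-then-z-scored trait matrix with the transform parameters retained.

    ``values[i, j] = (log10(raw[i, j]) - column_means[j]) / column_sds[j]``
    where means and SDs (sample SD, n-1 denominator) are taken over the
    log10-transformed column.
    """

    species_ids: list[str]
    trait_names: list[str]
    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray

    def column(self, trait: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(trait)]

    def inverse(self) -> pd.DataFrame:
        """De-standardize and exponentiate back to the raw trait scale."""
        log10 = self.values * self.column_sds + self.column_means
        return pd.DataFrame(
            10.0 ** log10, index=self.species_ids, columns=self.trait_names
        )


def read_trait_table(path, metadata_path=None) -> TraitTable:
    """Read a traits CSV (and optionally a metadata CSV) into a TraitTable.

    The traits CSV has columns ``species_id``, the six trait columns, and an
    optional ``imputed`` column holding semicolon-separated trait names
    (possibly empty) flagging values estimated from related species.
    """
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise TraitValidationError("traits CSV lacks a species_id column")
    missing = [c for c in TRAIT_NAMES if c not in df.columns]
    if missing:
        raise TraitValidationError(f"traits CSV missing columns: {missing}")
    for col in TRAIT_NAMES:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise TraitValidationError(
                f"non-numeric value in column {col!r} for species "
                f"{bad['species_id'].iloc[0]!r}"
            )
    df = df.set_index("species_id")
    traits = df[list(TRAIT_NAMES)].apply(pd.to_numeric)
    imputed = pd.DataFrame(False, index=df.index, columns=list(TRAIT_NAMES))
    if "imputed" in df.columns:
        for sid, cell in df["imputed"].items():
            if isinstance(cell, str) and cell.strip():
                for name in cell.split(";"):
                    name = name.strip()
                    if name not in TRAIT_NAMES:
                        raise TraitValidationError(
                            f"species {sid!r}: unknown imputed trait {name!r}"
                        )
                    imputed.at[sid, name] = True
    meta = read_species_metadata(metadata_path) if metadata_path else None
    return TraitTable(traits, imputed, meta)


def read_species_metadata(path) -> pd.DataFrame:
    """Read the species metadata CSV (biogeography, habitat, diet, taxonomy)."""
    meta = pd.read_csv(path)
    required = ["species_id", "biogeography", "habitat", "diet", *TAXONOMY_RANKS]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise TraitValidationError(f"metadata CSV missing columns: {missing}")
    if meta["species_id"].duplicated().any():
        dupes = meta.loc[meta["species_id"].duplicated(), "species_id"].tolist()
        raise TraitValidationError(f"duplicate species_id in metadata: {dupes}")
    return meta.set_index("species_id")


def transform_traits(table: TraitTable) -> StandardizedTraitMatrix:
    """log10-transform then z-score each trait column (sample SD).

    Raises on a zero-variance column: a trait identical across all species
    cannot be standardized and carries no ordination information.
    """
    if len(table) < 3:
        raise TraitValidationError("need at least 3 species to standardize traits")
    log10 = np.log10(table.traits.to_numpy(dtype=float))
    means = log10.mean(axis=0)
    sds = log10.std(axis=0, ddof=1)
    zero_var = [t for t, s in zip(TRAIT_NAMES, sds) if s == 0 or not np.isfinite(s)]
    if zero_var:
        raise TraitValidationError(
            f"zero variance in trait column(s) {zero_var}; cannot standardize"
        )
    z = (log10 - means) / sds
    return StandardizedTraitMatrix(
        species_ids=table.species_ids,
        trait_names=list(TRAIT_NAMES),
        values=z,
        column_means=means,
        column_sds=sds,
    )


def imputation_fraction(table: TraitTable) -> float:
    """Percentage of trait values flagged as imputed, rounded to 1 decimal."""
    n_flags = int(table.imputed.to_numpy().sum())
    total = len(table) * len(TRAIT_NAMES)
    return round(100.0 * n_flags / total, 1)


def write_trait_table(table: TraitTable, traits_path, metadata_path=None) -> None:
    """Write a TraitTable back to the CSV format :func:`read_trait_table` reads."""
    out = table.traits.copy()
    out["imputed"] = [
        ";".join(t for t in TRAIT_NAMES if table.imputed.at[sid, t])
        for sid in table.traits.index
    ]
    out.index.name = "species_id"
    out.to_csv(traits_path)
    if metadata_path is not None and table.meta is not None:
        meta = table.meta.copy()
        meta.index.name = "species_id"
        meta.to_csv(metadata_path)
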
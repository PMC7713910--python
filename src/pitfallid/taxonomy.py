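"""Nested taxonomic hierarchies and label lifting.

A :class:`TaxonomyTable` maps every species to its label at each higher rank
(default rank ladder: species, group, genus, subtribe, tribe, subfamily).
Species-level predictions from any classifier can then be *lifted* to a
coarser rank without retraining, which is what makes hierarchical scoring
possible: a prediction wrong at species may still be right at genus if the
predicted and true species are congeners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DEFAULT_RANKS: tuple[str, ...] = (
    "species",
    "group",
    "genus",
    "subtribe",
    "tribe",
    "subfamily",
)


class TaxonomyError(ValueError):
    """Invalid taxonomy table (duplicates, empty cells, broken nesting)."""


@dataclass(frozen=True)
class TaxonomyTable:
    """Species-to-higher-rank mapping over an ordered rank ladder.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per species, one column per rank.  Labels are exact,
        case-sensitive strings.
    ranks : tuple of str
        Rank names ordered from most specific (``ranks[0]``, the species
        rank) to least specific.
    """

    table: pd.DataFrame
    ranks: tuple[str, ...] = DEFAULT_RANKS
    _index: dict[str, int] = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        validate_taxonomy(self.table, self.ranks)
        species = self.table[self.ranks[0]]
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(species)}
        )

    @property
    def species(self) -> list[str]:
        return list(self.table[self.ranks[0]])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, species_label: str) -> bool:
        return species_label in self._index

    def ancestor(self, species_label: str, rank: str) -> str:
        """Label of ``species_label`` at ``rank``."""
        if rank not in self.ranks:
            raise TaxonomyError(
                f"unknown rank {rank!r}; ranks are {list(self.ranks)}"
            )
        try:
            row = self._index[species_label]
        except KeyError:
            raise TaxonomyError(
                f"unknown species {species_label!r}"
            ) from None
        return self.table.iloc[row][rank]

    def lift(self, labels, rank: str) -> list[str]:
        """Elementwise :meth:`ancestor`; preserves order and length."""
        return [self.ancestor(lab, rank) for lab in labels]

    def n_taxa(self, rank: str) -> int:
        if rank not in self.ranks:
            raise TaxonomyError(f"unknown rank {rank!r}")
        return self.table[rank].nunique()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def validate_taxonomy(table: pd.DataFrame, ranks) -> None:
    """Check uniqueness, completeness and proper nesting; raise on failure."""
    missing = [r for r in ranks if r not in table.columns]
    if missing:
        raise TaxonomyError(f"missing rank columns: {missing}")
    sub = table[list(ranks)]
    if sub.isna().any().any() or (sub.astype(str) == "").any().any():
        bad = sub.columns[sub.isna().any() | (sub.astype(str) == "").any()]
        raise TaxonomyError(
            f"empty cells in rank column(s) {list(bad)}; every species needs "
            "a label at every rank (use the nearest lower-rank label as a "
            "placeholder)"
        )
    species_col = ranks[0]
    dup = sub[species_col][sub[species_col].duplicated()]
    if len(dup):
        raise TaxonomyError(
            f"duplicate species row(s): {sorted(set(dup))}"
        )
    # Nesting: each label at rank r must map to exactly one label at rank r+1.
    for child, parent in zip(ranks[:-1], ranks[1:]):
        counts = sub.groupby(child, sort=False)[parent].nunique()
        offenders = counts[counts > 1]
        if len(offenders):
            name = offenders.index[0]
            parents = sorted(set(sub.loc[sub[child] == name, parent]))
            raise TaxonomyError(
                f"non-nested mapping: {child} {name!r} appears under "
                f"multiple {parent} labels {parents}"
            )


def load_taxonomy(path, ranks=None) -> TaxonomyTable:
    """Load and validate a taxonomy CSV (header = rank names, one row per species)."""
    table = pd.read_csv(path, dtype=str)
    if ranks is None:
        ranks = tuple(table.columns)
    return TaxonomyTable(table=table, ranks=tuple(ranks))


def ancestor(species_label: str, rank: str, tax: TaxonomyTable) -> str:
    return tax.ancestor(species_label, rank)


def lift_labels(labels, rank: str, tax: TaxonomyTable) -> list[str]:
    return tax.lift(labels, rank)
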
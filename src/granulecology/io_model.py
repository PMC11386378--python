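"""Data model and table I/O for granule-community count data.

The universal input is a taxa × samples table of non-negative integer
counts (ASV or genus level), accompanied by a taxonomy lineage table and a
sample metadata table describing the incubation design: 16 untreated
"ORIGINAL" granules plus nine micro-batch-reactor conditions (C1–C9) with
three replicate granules each.

All tables are tab-separated UTF-8 with a header row; the first column of
a count table is headed ``taxon_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TAXON_COL = "taxon_id"
UNKNOWN_GENUS = "unknowns"

#: The ten design groups: untreated granules plus the nine conditions.
ORIGINAL = "ORIGINAL"
CONDITIONS = tuple(f"C{i}" for i in range(1, 10))
GROUPS = (ORIGINAL,) + CONDITIONS

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Incubation parameters for each condition group (pH, temperature in °C,
#: substrate, cobalt status). C1 is the baseline "plate effect" condition
#: replicating the source-reactor regime; the others each vary one factor.
CONDITION_PARAMS: dict[str, dict[str, object]] = {
    "C1": dict(pH=7, temperature_C=37, substrate="VFA_MIX", cobalt="supplied"),
    "C2": dict(pH=4, temperature_C=37, substrate="VFA_MIX", cobalt="supplied"),
    "C3": dict(pH=10, temperature_C=37, substrate="VFA_MIX", cobalt="supplied"),
    "C4": dict(pH=7, temperature_C=23, substrate="VFA_MIX", cobalt="supplied"),
    "C5": dict(pH=7, temperature_C=37, substrate="CELLULOSE", cobalt="supplied"),
    "C6": dict(pH=7, temperature_C=37, substrate="GLUCOSE", cobalt="supplied"),
    "C7": dict(pH=7, temperature_C=37, substrate="ACETATE", cobalt="supplied"),
    "C8": dict(pH=7, temperature_C=37, substrate="ACETATE", cobalt="deprived"),
    "C9": dict(pH=7, temperature_C=37, substrate="VFA_MIX", cobalt="deprived"),
}


class TableFormatError(ValueError):
    """Raised when an input table violates the expected dialect or invariants."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise TableFormatError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class CountMatrix:
    """Taxa × samples matrix of non-negative integer counts."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples), integer dtype

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise TableFormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"count shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa × {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        _check_unique(self.taxon_ids, "taxon ids")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.taxon_ids, name=TAXON_COL),
            columns=self.sample_ids,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_taxa(self, taxa) -> "CountMatrix":
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise KeyError(f"taxa not in matrix: {missing}")
        rows = [idx[t] for t in taxa]
        return CountMatrix(list(taxa), list(self.sample_ids), self.counts[rows])

    def select_samples(self, samples) -> "CountMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in samples]
        return CountMatrix(list(self.taxon_ids), list(samples), self.counts[:, cols])


@dataclass
class RelativeAbundanceMatrix:
    """Taxa × samples matrix of within-sample proportions (columns sum to 1)."""

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        colsums = self.values.sum(axis=0)
        if self.values.size and not np.allclose(colsums, 1.0, atol=1e-9):
            j = int(np.argmax(np.abs(colsums - 1.0)))
            raise TableFormatError(
                f"sample {self.sample_ids[j]!r} proportions sum to {colsums[j]!r}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.taxon_ids, name=TAXON_COL),
            columns=self.sample_ids,
        )


@dataclass
class TaxonomyTable:
    """Ranked lineages per taxon; genus may be missing (empty or 'unknowns')."""

    table: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.table.columns]
        if missing:
            raise TableFormatError(f"taxonomy table missing ranks: {missing}")
        _check_unique(self.table.index, "taxonomy taxon ids")

    def genus_of(self, taxon_id: str) -> str:
        g = self.table.loc[taxon_id, "genus"]
        if pd.isna(g) or str(g).strip() == "" or str(g) == UNKNOWN_GENUS:
            return UNKNOWN_GENUS
        return str(g)


@dataclass
class SampleFrame:
    """Sample metadata: design group, replicate index and incubation parameters."""

    table: pd.DataFrame  # index sample_id; columns group, replicate, pH, ...

    REQUIRED = ("group", "replicate")

    def __post_init__(self) -> None:
        for c in self.REQUIRED:
            if c not in self.table.columns:
                raise TableFormatError(f"metadata missing column {c!r}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise TableFormatError(f"unknown design groups: {sorted(bad)}")
        _check_unique(self.table.index, "sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def groups_of(self, sample_ids) -> np.ndarray:
        return self.table.loc[list(sample_ids), "group"].to_numpy()

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    @classmethod
    def default_design(
        cls, n_original: int = 16, n_replicates: int = 3
    ) -> "SampleFrame":
        """The study layout: ``n_original`` untreated granules plus
        ``n_replicates`` granules for each of the nine conditions."""
        rows = []
        for r in range(1, n_original + 1):
            rows.append(dict(sample_id=f"ORIG_{r:02d}", group=ORIGINAL, replicate=r,
                             pH=np.nan, temperature_C=np.nan, substrate="",
                             cobalt=""))
        for cond in CONDITIONS:
            for r in range(1, n_replicates + 1):
                rows.append(dict(sample_id=f"{cond}_R{r}", group=cond, replicate=r,
                                 **CONDITION_PARAMS[cond]))
        df = pd.DataFrame(rows).set_index("sample_id")
        return cls(df)


# ---------------------------------------------------------------------------
# Readers / writers (tab-separated, UTF-8)
# ---------------------------------------------------------------------------

def read_count_table(path) -> CountMatrix:
    """Read a taxa × samples TSV count table.

    The header row carries sample ids; the first column (headed
    ``taxon_id``) carries taxon ids. Any non-integer or negative cell is an
    error naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != TAXON_COL:
        raise TableFormatError(
            f"first column must be {TAXON_COL!r}, got {df.columns[0]!r}"
        )
    taxa = df[TAXON_COL].astype(str).tolist()
    samples = list(df.columns[1:])
    raw = df[samples].to_numpy()
    counts = np.empty(raw.shape, dtype=np.int64)
    for j, s in enumerate(samples):
        for i, t in enumerate(taxa):
            cell = raw[i, j]
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"non-integer count {cell!r} at taxon {t!r}, sample {s!r}"
                ) from None
            if v < 0:
                raise TableFormatError(
                    f"negative count {v} at taxon {t!r}, sample {s!r}"
                )
            counts[i, j] = v
    return CountMatrix(taxa, samples, counts)


def write_count_table(m: CountMatrix, path) -> None:
    m.to_dataframe().to_csv(path, sep="\t")


def read_taxonomy_table(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index(TAXON_COL)
    return TaxonomyTable(df)


def write_taxonomy_table(tax: TaxonomyTable, path) -> None:
    tax.table.to_csv(path, sep="\t", index_label=TAXON_COL)


def read_sample_frame(path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path) -> None:
    frame.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Core table operations
# ---------------------------------------------------------------------------

def collapse_to_genus(m: CountMatrix, tax: TaxonomyTable) -> CountMatrix:
    """Collate ASV rows at genus level.

    Each genus row is the element-wise sum of its member ASV rows; ASVs
    without a genus assignment are pooled into a single ``unknowns`` row.
    Per-sample totals are conserved exactly.
    """
    missing = [t for t in m.taxon_ids if t not in tax.table.index]
    if missing:
        raise KeyError(f"taxa missing from taxonomy: {missing}")
    genera = [tax.genus_of(t) for t in m.taxon_ids]
    order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for g, row in zip(genera, m.counts):
        if g not in rows:
            rows[g] = row.astype(np.int64).copy()
            order.append(g)
        else:
            rows[g] += row
    return CountMatrix(order, list(m.sample_ids), np.array([rows[g] for g in order]))


def to_relative(m: CountMatrix) -> RelativeAbundanceMatrix:
    """Total-sum scaling: divide each column by its sum."""
    colsums = m.counts.sum(axis=0)
    if (colsums == 0).any():
        j = int(np.argmax(colsums == 0))
        raise ValueError(f"sample {m.sample_ids[j]!r} has zero total count")
    return RelativeAbundanceMatrix(
        list(m.taxon_ids), list(m.sample_ids), m.counts / colsums
    )


def top_n_taxa(m: CountMatrix, n: int) -> list[str]:
    """Taxa ranked by summed relative abundance, descending.

    Ties are broken lexicographically by taxon id; returns at most
    ``min(n, n_taxa)`` entries.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = to_relative(m).values.sum(axis=1)
    order = sorted(range(m.n_taxa), key=lambda i: (-totals[i], m.taxon_ids[i]))
    return [m.taxon_ids[i] for i in order[: min(n, m.n_taxa)]]
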
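"""From gOTU count tables to model-ready relative abundances.

Pipeline: collapse genome-resolved OTUs to species using a taxonomy
mapping (gOTUs without species-level annotation are dropped and
counted), map species onto the available reconstruction resource,
discard unmapped reads, apply a per-sample low-abundance cut-off, and
renormalise each sample to sum to one, while tracking the fraction of
the original reads each final column represents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "AbundanceTable",
    "collapse_to_species",
    "map_filter_normalise",
    "read_counts_tsv",
    "read_counts_biom_json",
    "write_abundance_tsv",
    "read_abundance_tsv",
]


@dataclass
class CountTable:
    """Taxa-by-sample nonnegative read counts plus optional taxonomy.

    ``taxonomy`` maps taxon id -> species name; taxa mapping to ``None``
    (or missing from the mapping) have no species-level annotation.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str | None] | None = None
    dropped: pd.Series | None = None  # reads dropped per sample at collapse

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")


@dataclass
class AbundanceTable:
    """Species-by-sample relative abundances in [0, 1].

    Each column sums to 1 over retained species; ``mapped_fraction``
    gives, per sample, the share of the original reads retained.
    """

    abundances: pd.DataFrame
    mapped_fraction: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def sample_abundances(self, sample: str) -> dict[str, float]:
        col = self.abundances[sample]
        return {sp: float(v) for sp, v in col.items() if v > 0}


def collapse_to_species(counts: CountTable) -> CountTable:
    """Sum gOTU rows with matching species taxonomy; drop unannotated ones."""
    if counts.counts.empty:
        raise ValueError("empty count table")
    if counts.taxonomy is None:
        raise ValueError("collapse_to_species requires a taxonomy mapping")
    species = pd.Series(
        {t: counts.taxonomy.get(t) for t in counts.counts.index}, dtype=object
    )
    annotated = species.dropna().index
    dropped_reads = counts.counts.drop(index=annotated).sum(axis=0)
    collapsed = (
        counts.counts.loc[annotated]
        .groupby(species.loc[annotated])
        .sum()
        .sort_index()
    )
    collapsed.index.name = "species"
    return CountTable(
        counts=collapsed,
        taxonomy={s: s for s in collapsed.index},
        dropped=dropped_reads,
    )


def map_filter_normalise(
    counts: CountTable,
    model_species: set[str],
    cutoff: float = 1e-5,
) -> AbundanceTable:
    """Map species to the reconstruction resource, cut low abundances, renormalise.

    Unmapped species are removed first; relative abundances are computed
    per sample over the mapped species; species strictly below ``cutoff``
    are removed per sample; each column is renormalised to 1.
    ``mapped_fraction`` is retained reads / total input reads per sample.
    """
    if not (0 <= cutoff < 1):
        raise ValueError("cutoff must be in [0, 1)")
    totals = counts.counts.sum(axis=0)
    mapped = counts.counts.loc[counts.counts.index.intersection(sorted(model_species))]
    mapped_totals = mapped.sum(axis=0)
    dead = mapped_totals[mapped_totals <= 0]
    if len(dead):
        raise ValueError(f"samples with zero mappable reads: {list(dead.index)}")
    rel = mapped / mapped_totals
    if cutoff > 0:
        rel = rel.where(rel >= cutoff, 0.0)
    retained_reads = mapped.where(rel > 0, 0.0).sum(axis=0)
    colsum = rel.sum(axis=0)
    if (colsum <= 0).any():
        bad = list(colsum[colsum <= 0].index)
        raise ValueError(f"samples with no species above the cut-off: {bad}")
    rel = rel / colsum
    rel = rel.loc[(rel > 0).any(axis=1)].sort_index()
    return AbundanceTable(
        abundances=rel,
        mapped_fraction=(retained_reads / totals).astype(float),
    )


# ---------------------------------------------------------------------------
# I/O

def read_counts_tsv(path: str, taxonomy_path: str | None = None) -> CountTable:
    """Read a taxa x samples TSV; optional 2-column taxonomy TSV (taxon, species)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = None
    if taxonomy_path is not None:
        tx = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        col = tx.columns[0]
        taxonomy = {
            t: (None if pd.isna(s) or s == "" else str(s)) for t, s in tx[col].items()
        }
    return CountTable(counts=df, taxonomy=taxonomy)


def read_counts_biom_json(path: str) -> CountTable:
    """Read a BIOM-format JSON table (sparse or dense), counts only."""
    with open(path) as fh:
        d = json.load(fh)
    rows = [r["id"] for r in d["rows"]]
    cols = [c["id"] for c in d["columns"]]
    mat = np.zeros((len(rows), len(cols)))
    if d.get("matrix_type") == "dense":
        mat[:] = np.asarray(d["data"], dtype=float)
    else:
        for i, j, v in d["data"]:
            mat[int(i), int(j)] = float(v)
    taxonomy = None
    if d["rows"] and d["rows"][0].get("metadata"):
        taxonomy = {}
        for r in d["rows"]:
            md = r.get("metadata") or {}
            taxonomy[r["id"]] = md.get("species")
    return CountTable(counts=pd.DataFrame(mat, index=rows, columns=cols), taxonomy=taxonomy)


def write_abundance_tsv(table: AbundanceTable, path: str) -> None:
    """Write species x samples TSV with a ``#mapped_fraction`` header row."""
    with open(path, "w") as fh:
        fracs = "\t".join(
            f"{table.mapped_fraction.get(s, float('nan')):.10g}" for s in table.abundances.columns
        )
        fh.write(f"#mapped_fraction\t{fracs}\n")
        table.abundances.to_csv(fh, sep="\t")


def read_abundance_tsv(path: str) -> AbundanceTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if header[0] != "#mapped_fraction":
        raise ValueError(f"{path}: missing #mapped_fraction header row")
    fracs = pd.Series([float(x) for x in header[1:]], index=df.columns, dtype=float)
    return AbundanceTable(abundances=df, mapped_fraction=fracs)
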
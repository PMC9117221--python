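"""Readers and writers for count tables, metadata, trees, and distance matrices.

Tabular formats are plain TSV (tab-separated, UTF-8, ``#`` comment lines
ignored, first column is the row id).  BIOM support is the JSON dialect
(BIOM 1.0); the HDF5 dialect is not handled.  Trees are newick via
scikit-bio; distance matrices round-trip through square TSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "CountTable",
    "read_counts",
    "write_counts",
    "aggregate_to_rank",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_tree",
    "write_tree",
]

#: metadata columns holding binary questionnaire flags ("yes"/"no"/missing)
CHRONIC_FLAGS = ("cystic_fibrosis", "down_syndrome", "celiac")
LIFESTYLE_FLAGS = ("smoking", "yeast", "antibiotics", "hypertension")

RELATIONSHIPS = ("sibling", "twin", "partner", "parent-child", "grandparent-grandchild")


@dataclass
class CountTable:
    """ASV (or genus/phylum) by sample table of nonnegative integer counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Taxa in rows, samples in columns, integer dtype.
    taxonomy : pandas.DataFrame
        Indexed by taxon id with at least ``genus`` and ``phylum`` columns;
        unknown labels are the string ``"unclassified"``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.taxonomy is None:
            self.taxonomy = pd.DataFrame(
                {"genus": "unclassified", "phylum": "unclassified"},
                index=self.counts.index,
            )
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate taxon ids in count table")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise ValueError(
                    f"non-integer count at taxon {c.index[bad[0]]!r}, "
                    f"sample {c.columns[bad[1]]!r}"
                )
            self.counts = c = c.round().astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at taxon {c.index[bad[0]]!r}, "
                f"sample {c.columns[bad[1]]!r}"
            )
        missing = c.index.difference(self.taxonomy.index)
        if len(missing):
            warnings.warn(
                f"{len(missing)} taxa lack a lineage record; labelled unclassified"
            )
            fill = pd.DataFrame(
                {"genus": "unclassified", "phylum": "unclassified"}, index=missing
            )
            self.taxonomy = pd.concat([self.taxonomy, fill])
        self.taxonomy = self.taxonomy.loc[c.index]

    # -- convenience -----------------------------------------------------
    @property
    def taxon_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def matrix(self) -> np.ndarray:
        """Counts as a samples x taxa float array (analysis orientation)."""
        return self.counts.to_numpy().T.astype(float)


def _lineage_string(genus: str, phylum: str) -> str:
    return f"p__{phylum}; g__{genus}"


def _parse_lineage(s: str) -> tuple[str, str]:
    genus = phylum = "unclassified"
    for tok in str(s).split(";"):
        tok = tok.strip()
        if tok.startswith("g__") and tok[3:]:
            genus = tok[3:]
        elif tok.startswith("p__") and tok[3:]:
            phylum = tok[3:]
    return genus, phylum


def read_counts(path, format: str = "tsv") -> CountTable:
    """Read a count table with taxonomy from TSV or BIOM-JSON.

    The TSV layout is taxa rows x sample columns with a trailing
    ``lineage`` column (``p__<phylum>; g__<genus>``).  BIOM files are the
    JSON (1.0) dialect with lineage under observation metadata ``taxonomy``.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        df.index.name = None
        if "lineage" in df.columns:
            lineages = df.pop("lineage")
            parsed = [_parse_lineage(s) for s in lineages]
            taxonomy = pd.DataFrame(parsed, columns=["genus", "phylum"], index=df.index)
        else:
            warnings.warn("no lineage column; all taxa labelled unclassified")
            taxonomy = None
        _check_numeric(df)
        return CountTable(df.astype(np.int64), taxonomy)
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros(doc["shape"], dtype=np.int64)
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(doc["data"])
        lineage = []
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            tax = md.get("taxonomy")
            lineage.append("; ".join(tax) if tax else "")
        taxonomy = pd.DataFrame(
            [_parse_lineage(s) for s in lineage], columns=["genus", "phylum"], index=taxa
        )
        return CountTable(pd.DataFrame(mat, index=taxa, columns=samples), taxonomy)
    raise ValueError(f"unknown count-table format {format!r}")


def _check_numeric(df: pd.DataFrame) -> None:
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric counts in sample column {col!r}")
        bad = df.index[(df[col] < 0)]
        if len(bad):
            raise ValueError(f"negative count at taxon {bad[0]!r}, sample {col!r}")
        frac = df[col] != np.round(df[col])
        if frac.any():
            raise ValueError(
                f"non-integer count at taxon {df.index[frac][0]!r}, sample {col!r}"
            )


def write_counts(table: CountTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        df = table.counts.copy()
        df["lineage"] = [
            _lineage_string(g, p)
            for g, p in zip(table.taxonomy["genus"], table.taxonomy["phylum"])
        ]
        df.to_csv(path, sep="\t", index_label="taxon_id")
        return
    if format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "oralmicro",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": list(table.counts.shape),
            "rows": [
                {
                    "id": t,
                    "metadata": {
                        "taxonomy": [
                            f"p__{table.taxonomy.loc[t, 'phylum']}",
                            f"g__{table.taxonomy.loc[t, 'genus']}",
                        ]
                    },
                }
                for t in table.taxon_ids
            ],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown count-table format {format!r}")


def aggregate_to_rank(table: CountTable, rank: str) -> CountTable:
    """Sum counts over taxa sharing a ``genus`` or ``phylum`` label.

    Unclassified taxa are kept distinct per parent lineage: an
    unclassified genus within phylum X becomes ``unclassified_X`` rather
    than being pooled with unclassified genera of other phyla.
    """
    if rank not in ("genus", "phylum"):
        raise ValueError(f"rank must be 'genus' or 'phylum', got {rank!r}")
    if rank not in table.taxonomy.columns:
        raise ValueError(f"rank {rank!r} absent from all lineages")
    labels = table.taxonomy[rank].copy()
    # refuse only when the lineage carries no information at this rank or
    # above; all-unclassified genera under known phyla still aggregate
    uninformative = (labels == "unclassified").all()
    if rank == "genus":
        uninformative &= (table.taxonomy["phylum"] == "unclassified").all()
    if len(labels) and uninformative:
        raise ValueError(f"rank {rank!r} absent from all lineages")
    if rank == "genus":
        parent = table.taxonomy["phylum"]
        mask = labels == "unclassified"
        labels[mask] = "unclassified_" + parent[mask].astype(str)
    grouped = table.counts.groupby(labels, sort=True).sum()
    if rank == "genus":
        tax = pd.DataFrame(
            {
                "genus": grouped.index,
                "phylum": [
                    table.taxonomy.loc[labels == g, "phylum"].iloc[0]
                    for g in grouped.index
                ],
            },
            index=grouped.index,
        )
    else:
        tax = pd.DataFrame(
            {"genus": "unclassified", "phylum": grouped.index}, index=grouped.index
        )
    return CountTable(grouped, tax)


# -- sample metadata ----------------------------------------------------

ALL_FLAGS = CHRONIC_FLAGS + LIFESTYLE_FLAGS


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample metadata table.

    Required columns: ``age``, ``gender``, ``region``.  Binary flags take
    values ``yes``/``no`` or missing (NaN).  Ages outside [0, 120] raise.
    Adds a ``chronic_disorder_any`` boolean column if absent.
    """
    meta = meta.copy()
    for col in ("age", "gender", "region"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    ages = pd.to_numeric(meta["age"], errors="coerce")
    bad = ages.dropna()
    if ((bad < 0) | (bad > 120)).any():
        raise ValueError("age outside [0, 120]")
    meta["age"] = ages
    for flag in ALL_FLAGS:
        if flag in meta.columns:
            vals = meta[flag].dropna().unique()
            extra = set(map(str, vals)) - {"yes", "no"}
            if extra:
                raise ValueError(f"flag {flag!r} has values outside yes/no: {extra}")
    if "chronic_disorder_any" not in meta.columns:
        present = [f for f in CHRONIC_FLAGS if f in meta.columns]
        if present:
            meta["chronic_disorder_any"] = (
                meta[present].eq("yes").any(axis=1).astype(bool)
            )
        else:
            meta["chronic_disorder_any"] = False
    return meta


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# -- distance matrices and trees ----------------------------------------


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path))


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path))
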
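"""Tabular I/O and canonical identifiers for the ceRNA pipeline.

Every matrix the pipeline touches is oriented features x samples and
serialized as plain TSV: the first column holds feature identifiers, the
header row holds sample identifiers.  Interaction tables are two-column
edge lists, gene sets use the GMT convention (set name, description, then
tab-separated members).

Ensembl-style version suffixes (``ENSG00000141510.16``) are stripped on
ingestion so that cross-cohort intersection keys on stable identifiers.
Missing values are encoded with NA tokens; how they are handled is up to
the consuming stage (per-model sample dropping in regulator selection).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TUMOUR = "tumour"
NORMAL = "normal"
GROUP_LABELS = (TUMOUR, NORMAL)
FEATURE_CLASSES = ("mRNA", "lncRNA", "miRNA")

#: columns of the serialized ceRNA network table
NETWORK_COLUMNS = (
    "pair_key",
    "rna_a",
    "rna_b",
    "shared_mirna_count",
    "pearson_r",
    "hypergeom_p",
    "mscor",
    "mscor_p_adj",
)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_version(feature_id: str) -> str:
    """Drop a trailing Ensembl version suffix (``.N``) from an identifier."""
    return _VERSION_SUFFIX.sub("", feature_id)


# ---------------------------------------------------------------------------
# pair keys
# ---------------------------------------------------------------------------


def make_pair_key(id_a: str, id_b: str) -> str:
    """Canonical key ``idA_idB`` for an unordered RNA pair.

    The lexicographically smaller identifier comes first, so the key is
    symmetric in its arguments and injective on unordered pairs.  It is the
    join key for the cross-cancer one-way frequency table.

    Raises
    ------
    ValueError
        If the two identifiers are equal (self-pairs are not ceRNA pairs),
        empty, or contain the ``_`` separator themselves.
    """
    if id_a == id_b:
        raise ValueError(f"self-pair is not a valid ceRNA pair: {id_a!r}")
    for x in (id_a, id_b):
        if not x:
            raise ValueError("empty identifier in pair key")
        if "_" in x:
            raise ValueError(f"identifier may not contain '_': {x!r}")
    return f"{id_a}_{id_b}" if id_a < id_b else f"{id_b}_{id_a}"


def split_pair_key(key: str) -> tuple[str, str]:
    """Inverse of :func:`make_pair_key`."""
    a, sep, b = key.partition("_")
    if not sep or not a or not b or "_" in b:
        raise ValueError(f"malformed pair key: {key!r}")
    return a, b


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountsMatrix:
    """Raw RNA/miRNA counts, features x samples, with sample group labels.

    Attributes
    ----------
    values : pandas.DataFrame
        Non-negative integer counts, index = feature ids, columns = sample
        ids.
    group : pandas.Series
        Per-sample label in {"tumour", "normal"}, indexed by sample id.
    feature_class : pandas.Series
        Per-feature label in {"mRNA", "lncRNA", "miRNA"}, indexed by
        feature id.
    """

    values: pd.DataFrame
    group: pd.Series
    feature_class: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "feature")
        _check_unique(v.columns, "sample")
        if v.shape[0] == 0:
            raise ValueError("no features")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts matrix contains non-numeric values")
        if np.isnan(arr.astype(float)).any():
            raise ValueError("counts matrix contains missing values")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at feature {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        if (arr != np.floor(arr)).any():
            r, c = np.argwhere(arr != np.floor(arr))[0]
            raise ValueError(
                f"non-integer count at feature {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        self.group = self.group.reindex(v.columns)
        if self.group.isna().any():
            missing = self.group.index[self.group.isna()][0]
            raise ValueError(f"sample {missing!r} has no group label")
        bad = set(self.group.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        self.feature_class = self.feature_class.reindex(v.index)
        if self.feature_class.isna().any():
            missing = self.feature_class.index[self.feature_class.isna()][0]
            raise ValueError(f"feature {missing!r} has no class label")
        bad = set(self.feature_class.unique()) - set(FEATURE_CLASSES)
        if bad:
            raise ValueError(f"unknown feature class(es): {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumour_samples(self) -> list[str]:
        return list(self.group.index[self.group == TUMOUR])

    @property
    def normal_samples(self) -> list[str]:
        return list(self.group.index[self.group == NORMAL])

    def subset_features(self, feature_ids: Iterable[str]) -> "CountsMatrix":
        ids = [f for f in self.values.index if f in set(feature_ids)]
        return CountsMatrix(
            self.values.loc[ids], self.group.copy(), self.feature_class.loc[ids]
        )


@dataclass
class GeneValueMatrix:
    """Gene-level regulator values (CNA or DM beta) over tumour samples.

    DM values are methylation beta values — methylated probe intensity over
    total intensity — and must lie in [0, 1]; CNA values are unconstrained
    reals.  NAs are permitted and handled downstream.
    """

    values: pd.DataFrame
    kind: str  # "CNA" | "DM"

    def __post_init__(self) -> None:
        if self.kind not in ("CNA", "DM"):
            raise ValueError(f"kind must be 'CNA' or 'DM', got {self.kind!r}")
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        if self.kind == "DM":
            arr = self.values.to_numpy(dtype=float)
            finite = np.isfinite(arr)
            if ((arr < 0) | (arr > 1))[finite].any():
                bad = np.argwhere(finite & ((arr < 0) | (arr > 1)))[0]
                raise ValueError(
                    "DM beta value outside [0, 1] at feature "
                    f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
                )


@dataclass(frozen=True)
class InteractionTable:
    """A set of directed regulator edges of one kind."""

    edges: frozenset  # of (source_id, target_id)
    kind: str  # "miRNA->mRNA" | "miRNA->lncRNA" | "TF->gene"

    def __post_init__(self) -> None:
        for s, t in self.edges:
            if not s or not t:
                raise ValueError("interaction with empty source or target id")

    def sources_for(self, target_id: str) -> set:
        """All regulators with an edge into ``target_id``."""
        return {s for s, t in self.edges if t == target_id}

    def by_target(self) -> dict:
        out: dict = {}
        for s, t in self.edges:
            out.setdefault(t, set()).add(s)
        return out


@dataclass
class RegulatorBundle:
    """Per-cohort regulator data feeding the per-gene models."""

    cna: GeneValueMatrix
    dm: GeneValueMatrix
    mirna_mrna: InteractionTable
    mirna_lncrna: InteractionTable
    tf_gene: InteractionTable

    def mirna_candidates(self, target_id: str, target_class: str) -> set:
        table = self.mirna_mrna if target_class == "mRNA" else self.mirna_lncrna
        return table.sources_for(target_id)

    def tf_candidates(self, target_id: str) -> set:
        return self.tf_gene.sources_for(target_id)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions (GMT)."""

    sets: dict = field(default_factory=dict)  # name -> set of gene ids
    descriptions: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> set:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _check_unique(index: Iterable[str], what: str) -> None:
    idx = pd.Index(index)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicated {what} identifier: {dup!r}")


def _read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features-x-samples TSV, checking duplicates before pandas
    gets a chance to mangle them."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    _check_unique(samples, "sample")
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index = df.index.astype(str).map(strip_version)
    _check_unique(df.index, "feature")
    if df.shape[0] == 0:
        raise ValueError(f"no features in {path}")
    return df


def read_counts(path: str | Path, class_map_path: str | Path,
                groups_path: str | Path | None = None,
                group: pd.Series | None = None) -> CountsMatrix:
    """Read a raw-counts TSV plus its feature-class map (and group labels).

    Parameters
    ----------
    path
        TSV of non-negative integer counts, features x samples.
    class_map_path
        Two-column TSV ``feature_id<TAB>class`` with class in
        {mRNA, lncRNA, miRNA}.
    groups_path, group
        Sample group labels, either as a two-column TSV
        ``sample_id<TAB>group`` or as an in-memory Series.  Exactly one
        must be provided.
    """
    df = _read_matrix(path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric count at feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    classes = pd.read_csv(class_map_path, sep="\t", header=None,
                          names=["feature_id", "feature_class"], comment="#")
    classes["feature_id"] = classes["feature_id"].astype(str).map(strip_version)
    class_map = classes.set_index("feature_id")["feature_class"]
    if group is None:
        if groups_path is None:
            raise ValueError("provide groups_path or group")
        g = pd.read_csv(groups_path, sep="\t", header=None,
                        names=["sample_id", "group"], comment="#")
        group = g.set_index("sample_id")["group"]
    return CountsMatrix(numeric.astype(np.int64), group, class_map)


def read_gene_values(path: str | Path, kind: str) -> GeneValueMatrix:
    """Read a CNA or DM matrix; DM values are validated against [0, 1]."""
    df = _read_matrix(path).apply(pd.to_numeric, errors="coerce")
    return GeneValueMatrix(df.astype(float), kind)


def read_interactions(path: str | Path, kind: str) -> InteractionTable:
    """Read a two-column ``source<TAB>target`` edge list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"],
                     comment="#", dtype=str)
    edges = frozenset(
        (strip_version(s), strip_version(t))
        for s, t in zip(df["source"], df["target"])
    )
    return InteractionTable(edges, kind)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: name, description, then members."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line!r}")
            name, desc, members = fields[0], fields[1], fields[2:]
            coll.sets[name] = {m for m in members if m}
            coll.descriptions[name] = desc
    return coll


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, time, event."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table needs columns {sorted(required)}")
    if (df["time"] < 0).any():
        raise ValueError("negative follow-up time in clinical table")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# writers (all round-trip stable)
# ---------------------------------------------------------------------------


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    rows = sorted(table.edges)
    with open(path, "w") as fh:
        for s, t in rows:
            fh.write(f"{s}\t{t}\n")


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.sets):
            desc = coll.descriptions.get(name, "na")
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def write_network(net, path: str | Path, passed_only: bool = True) -> None:
    """Serialize a ceRNA network to TSV with the canonical column set."""
    df = net.to_frame(passed_only=passed_only)
    df.loc[:, list(NETWORK_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> pd.DataFrame:
    """Read a serialized network table back as a DataFrame."""
    return pd.read_csv(path, sep="\t")
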
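"""Cross-cohort intersection of ceRNA networks.

Passed pairs from every cohort are compiled into a one-way frequency
table keyed on the canonical pair key.  A pair with frequency equal to
the number of cohorts belongs to the shared network of all cohorts; with
frequency 2 or 3 it belongs to the respective cohort combination.  Both
"exactly these cohorts" (the default presentation, which partitions the
pairs) and "at least these cohorts" tabulations are produced, with pair
counts and unique-gene counts per combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .cerna_inference import unique_rna_count
from .formats_io import split_pair_key


@dataclass
class SharedCeRNATable:
    """One-way frequency table of pair keys across cohorts."""

    cohorts: list
    membership: pd.DataFrame  # bool matrix, pair_key x cohort, plus "frequency"

    @property
    def frequency(self) -> pd.Series:
        return self.membership["frequency"]

    def pairs_with_frequency(self, k: int) -> set:
        return set(self.membership.index[self.membership["frequency"] == k])

    def pairs_in_exactly(self, cohort_subset) -> set:
        """Pairs present in precisely these cohorts and no others."""
        subset = set(cohort_subset)
        mask = pd.Series(True, index=self.membership.index)
        for c in self.cohorts:
            col = self.membership[c]
            mask &= col if c in subset else ~col
        return set(self.membership.index[mask])

    def pairs_in_at_least(self, cohort_subset) -> set:
        subset = set(cohort_subset)
        mask = pd.Series(True, index=self.membership.index)
        for c in subset:
            mask &= self.membership[c]
        return set(self.membership.index[mask])

    def combination_summary(self, min_size: int = 2) -> pd.DataFrame:
        """Per-combination pair and unique-gene counts, exact and at-least."""
        rows = []
        for r in range(min_size, len(self.cohorts) + 1):
            for subset in combinations(self.cohorts, r):
                exact = self.pairs_in_exactly(subset)
                atleast = self.pairs_in_at_least(subset)
                rows.append({
                    "combination": "&".join(subset),
                    "n_cohorts": r,
                    "pairs_exact": len(exact),
                    "unique_genes_exact": unique_rna_count(exact),
                    "pairs_at_least": len(atleast),
                    "unique_genes_at_least": unique_rna_count(atleast),
                })
        return pd.DataFrame(rows)

    def genes_in_exactly(self, cohort_subset) -> set:
        genes: set = set()
        for k in self.pairs_in_exactly(cohort_subset):
            genes.update(split_pair_key(k))
        return genes


def _pair_keys(network) -> set:
    if hasattr(network, "passed_keys"):
        return set(network.passed_keys())
    return set(network)


def intersect_networks(networks) -> SharedCeRNATable:
    """Build the shared-pair table from per-cohort networks.

    ``networks`` is a mapping cohort id -> CeRNANetwork (or set of pair
    keys), or a sequence of (cohort_id, network) tuples; duplicate cohort
    ids raise.  At least two cohorts are required.
    """
    if isinstance(networks, dict):
        items = list(networks.items())
    else:
        items = list(networks)
    ids = [c for c, _ in items]
    if len(set(ids)) != len(ids):
        dup = next(c for c in ids if ids.count(c) > 1)
        raise ValueError(f"duplicate cohort id: {dup!r}")
    if len(items) < 2:
        raise ValueError("need at least 2 cohorts to intersect")
    keysets = {c: _pair_keys(net) for c, net in items}
    all_keys = sorted(set().union(*keysets.values()))
    data = {c: [k in keysets[c] for k in all_keys] for c in ids}
    membership = pd.DataFrame(data, index=pd.Index(all_keys, name="pair_key"))
    membership["frequency"] = membership[ids].sum(axis=1)
    return SharedCeRNATable(cohorts=ids, membership=membership)


def unique_gene_count(pairs) -> int:
    """Size of the union of both members over all pair keys."""
    return unique_rna_count(pairs)
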
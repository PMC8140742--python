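"""Parameter-grid expansion and redundancy filtering of encoding specs.

The full experiment is the union, over encoder groups, of the Cartesian
product of each group's parameter axes.  Because many resulting encoded
datasets are near-duplicates (correlated amino-acid indices; adjacent
parameter values), two greedy filters reduce the set before benchmarking:

* :func:`filter_aaindex` clusters amino-acid index tables on the absolute
  Pearson correlation of their 20-value vectors and keeps one
  representative per cluster;
* :func:`filter_specs_by_probe` encodes a small probe dataset under every
  spec and greedily drops any spec whose matrix has an adjusted
  RV-coefficient above a threshold with an already-retained spec.

Both filters are deterministic under a fixed input order and idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from pepbench.datasets import PeptideDataset
from pepbench.encode import EncodedDataset, EncodingSpec, IndexTable, encode, registry
from pepbench.errors import InvalidParameterError, RegistryError, UndefinedStatisticError
from pepbench.stats import rv_adjusted

logger = logging.getLogger(__name__)


@dataclass
class ParameterGrid:
    """One encoder group with an ordered map of parameter axes."""

    group: str
    axes: dict[str, list] | None = None

    def __post_init__(self) -> None:
        self.axes = dict(self.axes or {})
        for name, values in self.axes.items():
            if not values:
                raise InvalidParameterError(f"{self.group}: axis {name!r} is empty")

    @property
    def size(self) -> int:
        """Number of specs this grid expands to (product of deduplicated axis sizes)."""
        out = 1
        for values in self.axes.values():
            out *= len(dict.fromkeys(values))
        return out


def expand_grid(grids: Sequence[ParameterGrid]) -> list[EncodingSpec]:
    """Expand grids into the union of per-group Cartesian products.

    Axis values are deduplicated (first occurrence wins) before the
    product; a parameterless grid yields exactly one spec.  The total
    count is the sum over groups of the product of axis sizes.
    """
    specs: list[EncodingSpec] = []
    seen: set = set()
    for grid in grids:
        if grid.group not in registry:
            raise RegistryError(f"unknown encoding group {grid.group!r}")
        names = list(grid.axes)
        value_lists = [list(dict.fromkeys(grid.axes[n])) for n in names]
        for combo in product(*value_lists):
            spec = EncodingSpec(grid.group, dict(zip(names, combo)))
            if spec not in seen:
                seen.add(spec)
                specs.append(spec)
    return specs


def _index_correlation(a: IndexTable, b: IndexTable) -> float:
    return float(np.corrcoef(a.as_array(), b.as_array())[0, 1])


def filter_aaindex(indices: Sequence[IndexTable], threshold: float = 0.8) -> list[IndexTable]:
    """Greedy single-link clustering of index tables on |Pearson r|.

    Scanning the indices in input order, an index joins the first existing
    cluster containing a member with ``|r| >= threshold``, else founds a
    new cluster.  Each cluster is represented by its highest-variance
    member (ties broken by lexicographic identifier).  The output is
    ordered by cluster foundation and is idempotent.
    """
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError(f"threshold must lie in (0, 1], got {threshold}")
    if not indices:
        raise InvalidParameterError("need at least one index")
    for ix in indices:
        ix.standardized()  # rejects zero-variance tables
    clusters: list[list[IndexTable]] = []
    for ix in indices:
        for cluster in clusters:
            if any(abs(_index_correlation(ix, m)) >= threshold for m in cluster):
                cluster.append(ix)
                break
        else:
            clusters.append([ix])
    reps = []
    for cluster in clusters:
        reps.append(max(cluster, key=lambda t: (t.variance, [-ord(c) for c in t.identifier])))
    return reps


def filter_specs_by_probe(
    specs: Sequence[EncodingSpec],
    probe: PeptideDataset,
    threshold: float = 0.95,
) -> list[EncodingSpec]:
    """Greedy redundancy filter on encoded probe matrices.

    Specs are visited in the given order; a spec is dropped when its
    probe encoding has an adjusted RV-coefficient >= ``threshold`` with
    the encoding of any already-retained spec.  A spec that fails to
    encode the probe is logged and excluded (not fatal).
    """
    if not 0.0 < threshold <= 1.0:
        raise InvalidParameterError(f"threshold must lie in (0, 1], got {threshold}")
    kept: list[EncodingSpec] = []
    kept_matrices: list[EncodedDataset] = []
    for spec in specs:
        try:
            enc = encode(probe, spec)
        except Exception as exc:  # failing specs are skipped, not fatal
            logger.warning("probe filter: %s failed on probe (%s), excluded", spec.id, exc)
            continue
        redundant = False
        for prev_spec, prev in zip(kept, kept_matrices):
            shared = [rid for rid in enc.row_ids if rid in set(prev.row_ids)]
            if len(shared) < 3:
                continue
            try:
                rv = rv_adjusted(
                    enc.subset_rows(shared).matrix, prev.subset_rows(shared).matrix
                )
            except UndefinedStatisticError:
                continue
            if rv >= threshold:
                logger.info(
                    "probe filter: %s redundant with %s (RV_adj=%.3f)", spec.id, prev_spec.id, rv
                )
                redundant = True
                break
        if not redundant:
            kept.append(spec)
            kept_matrices.append(enc)
    return kept
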
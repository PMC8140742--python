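"""Pseudo K-tuple reduced amino-acid composition.

The sequence is first mapped to a reduced alphabet (a bundled cluster
family and cluster count), then gapped k-tuple relative frequencies are
counted: a tuple of size t with gap g covers positions
i, i+g+1, ..., i+(t-1)(g+1).  With clusters=20, ktuple=1 and gap=0 the
reduction is the identity and the encoder coincides with aac.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from pepbench.datasets import PeptideDataset
from pepbench.encode import tables
from pepbench.encode.base import EncodedDataset, EncodingSpec, TooShort, encode_rows, register
from pepbench.errors import InvalidParameterError


def _valid_clusters(v) -> bool:
    return isinstance(v, int) and any(v in fam for fam in tables.PSEKRAAC_FAMILIES.values())


@register(
    "psekraac",
    {
        "subtype": lambda v: v in tables.PSEKRAAC_FAMILIES,
        "clusters": _valid_clusters,
        "ktuple": lambda v: isinstance(v, int) and 1 <= v <= 3,
        "gap": lambda v: isinstance(v, int) and 0 <= v <= 9,
    },
    {"subtype": "type1", "clusters": 5, "ktuple": 2, "gap": 0},
)
def psekraac(
    dataset: PeptideDataset,
    subtype: str = "type1",
    clusters: int = 5,
    ktuple: int = 2,
    gap: int = 0,
    spec: EncodingSpec | None = None,
) -> EncodedDataset:
    """Gapped k-tuple frequencies over a reduced alphabet (clusters^ktuple features)."""
    spec = spec or EncodingSpec(
        "psekraac", {"subtype": subtype, "clusters": clusters, "ktuple": ktuple, "gap": gap}
    )
    family = tables.PSEKRAAC_FAMILIES[subtype]
    if clusters not in family:
        raise InvalidParameterError(
            f"psekraac {subtype}: no {clusters}-cluster reduction; "
            f"available: {sorted(family)}"
        )
    classes = family[clusters]
    gmap = tables.group_index(classes)
    names = [
        "psekraac." + ".".join(str(c) for c in t)
        for t in product(range(clusters), repeat=ktuple)
    ]
    span = (ktuple - 1) * (gap + 1) + 1

    def row(s: str) -> np.ndarray:
        n = len(s) - span + 1
        if n < 1:
            raise TooShort(f"length {len(s)} < tuple span {span}")
        cs = [gmap[a] for a in s]
        counts = np.zeros(clusters**ktuple)
        for i in range(n):
            code = 0
            for j in range(ktuple):
                code = code * clusters + cs[i + j * (gap + 1)]
            counts[code] += 1
        return counts / n

    return encode_rows(dataset, spec, names, row)
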
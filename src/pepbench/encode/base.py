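"""Encoding registry and the core encoded-dataset container.

An *encoding* is a pure function mapping an amino-acid sequence to a
fixed-length numeric vector.  Encoders are registered under a group name
together with the domain of each of their parameters; an
:class:`EncodingSpec` names one concrete instance (group + parameter
values).  Applying a spec to a dataset yields an :class:`EncodedDataset`:
one row per retained record, with records too short for the spec dropped
and logged rather than NA-filled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from pepbench.datasets import PeptideDataset
from pepbench.errors import EmptyEncodingError, InvalidParameterError, RegistryError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EncodingSpec:
    """One concrete encoding instance: registry group plus parameter values."""

    group: str
    params: tuple[tuple[str, object], ...] = ()

    def __init__(self, group: str, params: Mapping[str, object] | None = None):
        object.__setattr__(self, "group", group)
        items = tuple(sorted((params or {}).items()))
        object.__setattr__(self, "params", items)

    @property
    def param_dict(self) -> dict[str, object]:
        return dict(self.params)

    @property
    def id(self) -> str:
        """Stable human-readable identifier, e.g. ``cksaap(gmax=2)``."""
        if not self.params:
            return self.group
        inner = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.group}({inner})"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.id

    def to_json(self) -> str:
        return json.dumps({"group": self.group, "params": self.param_dict})

    @classmethod
    def from_json(cls, text: str) -> "EncodingSpec":
        obj = json.loads(text)
        return cls(obj["group"], obj.get("params", {}))


class TooShort(Exception):
    """Internal signal: a sequence cannot be encoded under the given spec."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass
class EncodedDataset:
    """Numeric feature matrix produced by one encoding spec.

    ``matrix`` has one row per retained record in input order; records the
    encoder could not handle are listed in ``dropped`` with a reason.
    """

    spec: EncodingSpec
    row_ids: list[str]
    feature_names: list[str]
    matrix: np.ndarray
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape != (len(self.row_ids), len(self.feature_names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"{self.spec.id}: non-finite values in encoded matrix")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.row_ids, columns=self.feature_names)

    def subset_rows(self, ids: Iterable[str]) -> "EncodedDataset":
        wanted = set(ids)
        keep = [i for i, rid in enumerate(self.row_ids) if rid in wanted]
        return EncodedDataset(
            self.spec,
            [self.row_ids[i] for i in keep],
            list(self.feature_names),
            self.matrix[keep],
            dict(self.dropped),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as CSV (id column + named features) with a JSON spec sidecar."""
        path = Path(path)
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".spec.json")
        sidecar.write_text(
            json.dumps(
                {
                    "group": self.spec.group,
                    "params": self.spec.param_dict,
                    "dropped": self.dropped,
                },
                indent=2,
            )
        )


@dataclass
class EncoderEntry:
    name: str
    func: Callable[..., EncodedDataset]
    param_domains: dict[str, Callable[[object], bool]]
    defaults: dict[str, object]
    doc: str = ""


#: Global registry of encoder groups.
registry: dict[str, EncoderEntry] = {}


def register(
    name: str,
    param_domains: dict[str, Callable[[object], bool]] | None = None,
    defaults: dict[str, object] | None = None,
):
    """Class decorator registering an encoder function under ``name``."""

    def deco(func: Callable[..., EncodedDataset]):
        registry[name] = EncoderEntry(
            name=name,
            func=func,
            param_domains=param_domains or {},
            defaults=defaults or {},
            doc=(func.__doc__ or "").strip().splitlines()[0] if func.__doc__ else "",
        )
        return func

    return deco


def validate_spec(spec: EncodingSpec) -> EncoderEntry:
    if spec.group not in registry:
        raise RegistryError(f"unknown encoding group {spec.group!r}")
    entry = registry[spec.group]
    for key, value in spec.params:
        if key not in entry.param_domains:
            raise RegistryError(f"{spec.group}: unknown parameter {key!r}")
        if not entry.param_domains[key](value):
            raise InvalidParameterError(f"{spec.group}: parameter {key}={value!r} outside domain")
    return entry


def encode(dataset: PeptideDataset, spec: EncodingSpec) -> EncodedDataset:
    """Apply one encoding spec to a dataset via the registry."""
    entry = validate_spec(spec)
    params = dict(entry.defaults)
    params.update(spec.param_dict)
    return entry.func(dataset, spec=EncodingSpec(spec.group, params), **params)


def encode_rows(
    dataset: PeptideDataset,
    spec: EncodingSpec,
    feature_names: list[str],
    row_fn: Callable[[str], np.ndarray],
) -> EncodedDataset:
    """Shared per-sequence driver: apply ``row_fn``, drop-and-log too-short records."""
    rows: list[np.ndarray] = []
    ids: list[str] = []
    dropped: dict[str, str] = {}
    for rec in dataset.records:
        try:
            rows.append(np.asarray(row_fn(rec.sequence), dtype=float))
        except TooShort as exc:
            dropped[rec.id] = exc.reason
            logger.info("%s: dropped %s (%s)", spec.id, rec.id, exc.reason)
        else:
            ids.append(rec.id)
    if not ids:
        raise EmptyEncodingError(f"{spec.id}: every record was dropped")
    return EncodedDataset(spec, ids, feature_names, np.vstack(rows), dropped)
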
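"""Tabular individual-level data with per-variable kind and role metadata.

A :class:`Dataset` wraps a pandas DataFrame (one row per individual) and
records, for every column, its statistical kind -- ``continuous`` or
``categorical`` with a declared level set -- and its causal role in the
study design (``instrument``, ``phenotype``, ``outcome``, ``confounder``
or ``score``).  The kind drives how a node is scored in network learning
(Gaussian vs multinomial); the role is bookkeeping used by the analysis
harnesses and the ground-truth maps of the simulators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

VALID_KINDS = frozenset({"continuous", "categorical"})
VALID_ROLES = frozenset({"instrument", "phenotype", "outcome", "confounder", "score"})


@dataclass
class Dataset:
    """Individuals x variables table with kind/role metadata.

    Parameters
    ----------
    values
        Numeric table, one row per individual.  No missing values.
    kinds
        Mapping column -> ``"continuous"`` | ``"categorical"``.
    roles
        Mapping column -> causal role.
    levels
        For each categorical column, the ordered tuple of admissible
        values.  Levels are declared (not inferred) so that degenerate
        bootstrap resamples keep a stable parameter count.
    """

    values: pd.DataFrame
    kinds: dict[str, str]
    roles: dict[str, str]
    levels: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        for col in cols:
            kind = self.kinds.get(col)
            if kind not in VALID_KINDS:
                raise ValueError(f"column {col!r} has invalid kind {kind!r}")
            role = self.roles.get(col)
            if role not in VALID_ROLES:
                raise ValueError(f"column {col!r} has invalid role {role!r}")
            if kind == "categorical" and col not in self.levels:
                self.levels[col] = tuple(sorted(pd.unique(self.values[col])))
        self.validate()

    # -- invariants -----------------------------------------------------

    def validate(self) -> None:
        """Check the container invariants; raise ValueError on violation."""
        if self.values.isna().any().any():
            raise ValueError("dataset contains missing values")
        for col, kind in self.kinds.items():
            if kind == "categorical":
                observed = set(pd.unique(self.values[col]))
                declared = set(self.levels[col])
                if not observed <= declared:
                    raise ValueError(
                        f"column {col!r} has values {observed - declared} "
                        f"outside declared levels {declared}"
                    )

    # -- accessors ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def var_names(self) -> list[str]:
        return list(self.values.columns)

    def column(self, name: str) -> np.ndarray:
        return np.asarray(self.values[name], dtype=float)

    def subset(self, columns: list[str]) -> "Dataset":
        """Restrict to a subset of columns, keeping metadata."""
        return Dataset(
            values=self.values[list(columns)].copy(),
            kinds={c: self.kinds[c] for c in columns},
            roles={c: self.roles[c] for c in columns},
            levels={c: self.levels[c] for c in columns if c in self.levels},
        )

    # -- I/O ------------------------------------------------------------

    def write(self, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write values as CSV plus a YAML sidecar with kinds/roles/levels."""
        csv_path = Path(csv_path)
        self.values.to_csv(csv_path, index=False)
        if meta_path is None:
            meta_path = csv_path.with_suffix(".meta.yaml")
        meta = {
            "kinds": dict(self.kinds),
            "roles": dict(self.roles),
            "levels": {k: list(v) for k, v in self.levels.items()},
        }
        Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def read(cls, csv_path: str | Path, meta_path: str | Path | None = None) -> "Dataset":
        csv_path = Path(csv_path)
        if meta_path is None:
            meta_path = csv_path.with_suffix(".meta.yaml")
        values = pd.read_csv(csv_path)
        meta = yaml.safe_load(Path(meta_path).read_text())
        return cls(
            values=values,
            kinds=dict(meta["kinds"]),
            roles=dict(meta["roles"]),
            levels={k: tuple(v) for k, v in meta.get("levels", {}).items()},
        )


def write_role_map(role_map: dict, path: str | Path) -> None:
    """Persist a ground-truth role map as JSON."""
    Path(path).write_text(json.dumps(role_map, indent=2, sort_keys=True))


def read_role_map(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
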
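"""Domain types and file I/O for expression matrices, module sets and gene sets.

The central containers are deliberately light: an expression matrix is a
features × samples array with identifier lists, a gene module is a named set
of feature identifiers, and a module set is an ordered, pairwise-disjoint
collection of modules plus the unassigned remainder.  Modules are treated as
simple sets throughout — no weights, no ordering of members.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneModule",
    "ModuleSet",
    "StabilityDistribution",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_module_set",
    "write_module_set",
]

#: Reserved module name used to mark unassigned features in module-set files.
UNASSIGNED_LABEL = "_unassigned_"

#: Versioned magic line for the bespoke module-set format.
MODULE_SET_MAGIC = "# sabre-module-set v1"

#: Header cell marking the feature-identifier column of an expression table.
FEATURE_HEADER = "feature_id"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class IdentifierError(ValueError):
    """Duplicate or unknown identifiers."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features × samples real-valued expression matrix.

    Rows are features (probe sets / genes), columns are samples.  Values are
    assumed to be on a log-like scale; the package never transforms them.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for label, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise IdentifierError(f"duplicate {label} identifiers")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=list(self.feature_ids), columns=list(self.sample_ids))
        frame.index.name = FEATURE_HEADER
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            feature_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, indices: Sequence[int], suffix_duplicates: bool = True) -> "ExpressionMatrix":
        """Column subset; repeated indices become distinct columns.

        Bootstrap resampling duplicates columns, so repeated sample ids are
        disambiguated with ``.b<k>`` suffixes to keep identifiers unique.
        """
        indices = list(indices)
        ids: list[str] = []
        seen: dict[str, int] = {}
        for i in indices:
            base = self.sample_ids[i]
            if base in seen:
                seen[base] += 1
                if not suffix_duplicates:
                    raise IdentifierError(f"duplicate sample id {base!r}")
                ids.append(f"{base}.b{seen[base]}")
            else:
                seen[base] = 0
                ids.append(base)
        return ExpressionMatrix(self.feature_ids, tuple(ids), self.values[:, indices])

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in keep]
        return ExpressionMatrix(tuple(keep), self.sample_ids, self.values[idx, :])


@dataclass(frozen=True)
class GeneModule:
    """A named set of feature identifiers."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"module {self.name!r} is empty")
        if self.name == UNASSIGNED_LABEL:
            raise ValueError(f"{UNASSIGNED_LABEL!r} is a reserved module name")

    @property
    def size(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ModuleSet:
    """Ordered, pairwise-disjoint modules plus the unassigned remainder.

    ``modules ∪ unassigned`` is the feature universe the modules were derived
    from; that universe is the population for all set-similarity and
    enrichment computations downstream.
    """

    modules: tuple[GeneModule, ...]
    unassigned: frozenset[str] = frozenset()
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        object.__setattr__(self, "unassigned", frozenset(self.unassigned))
        object.__setattr__(self, "provenance", dict(self.provenance))
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise IdentifierError("duplicate module names")
        counts: dict[str, int] = {}
        for m in self.modules:
            for g in m.members:
                counts[g] = counts.get(g, 0) + 1
        overlapping = sorted(g for g, c in counts.items() if c > 1)
        if overlapping:
            raise IdentifierError(f"features assigned to more than one module: {overlapping[:5]}")
        clash = set(counts) & self.unassigned
        if clash:
            raise IdentifierError(f"features both assigned and unassigned: {sorted(clash)[:5]}")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set(self.unassigned)
        for m in self.modules:
            out |= m.members
        return frozenset(out)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[GeneModule]:
        return iter(self.modules)

    def __getitem__(self, name: str) -> GeneModule:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    def sizes(self) -> dict[str, int]:
        return {m.name: m.size for m in self.modules}


@dataclass(frozen=True)
class StabilityDistribution:
    """Best-match similarity scores for one reference module across B replicates."""

    module_name: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D vector")
        if np.any((scores < 0) | (scores > 1)):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def n_bootstrap(self) -> int:
        return int(self.scores.size)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets, e.g. an MSigDB sub-collection read from GMT."""

    name: str
    sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        sets = {k: frozenset(v) for k, v in self.sets.items()}
        object.__setattr__(self, "sets", sets)
        for k, v in sets.items():
            if not v:
                raise ValueError(f"gene set {k!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: set[str] | frozenset[str]) -> "GeneSetCollection":
        """Intersect every set with the measured universe; drop emptied sets."""
        kept = {k: v & frozenset(universe) for k, v in self.sets.items()}
        return GeneSetCollection(self.name, {k: v for k, v in kept.items() if v})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited expression table: header row = sample ids, first column = feature ids.

    The top-left header cell, when present, must not declare the transposed
    orientation (``sample_id``): a transposed file is rejected rather than
    silently re-oriented.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0, comment=None)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"{path}: {exc}") from exc
    corner = frame.index.name
    if corner is not None and str(corner).strip().lower() == "sample_id":
        raise FormatError(
            f"{path}: header declares samples in rows; expected features x samples orientation"
        )
    feature_ids = [str(i) for i in frame.index]
    if len(set(feature_ids)) != len(feature_ids):
        dupes = frame.index[frame.index.duplicated()].unique()
        raise IdentifierError(f"{path}: duplicate feature identifiers {list(map(str, dupes[:5]))}")
    sample_ids = [str(c) for c in frame.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise IdentifierError(f"{path}: duplicate sample identifiers")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise FormatError(f"{path}: non-numeric value at feature {bad[0]!r}, sample {col!r}")
        if coerced.isna().any():
            missing = frame.index[coerced.isna()][0]
            raise FormatError(f"{path}: missing value at feature {missing!r}, sample {col!r}")
        frame[col] = coerced
    return ExpressionMatrix(tuple(feature_ids), tuple(sample_ids), frame.to_numpy(dtype=float))


def write_expression_matrix(x: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    x.to_frame().to_csv(path, sep=delimiter)


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``.

    Member identifiers listed more than once within a line are stored once
    (sets have set semantics); duplicate set names across lines are an error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}")
            set_name, _description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {set_name!r} has no members")
            if set_name in sets:
                raise IdentifierError(f"{path}:{lineno}: duplicate gene-set name {set_name!r}")
            sets[set_name] = frozenset(members)
    return GeneSetCollection(name or path.stem, sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for set_name, members in coll.sets.items():
            fh.write("\t".join([set_name, "na", *sorted(members)]) + "\n")


def write_module_set(ms: ModuleSet, path: str | Path) -> None:
    """Write the bespoke module-set TSV.

    Layout: a magic/version line, a ``# provenance: {...}`` JSON line, a
    column header, then one ``feature<TAB>module`` row per feature.  Unassigned
    features appear under the reserved label so the file round-trips the full
    universe.
    """
    with Path(path).open("w") as fh:
        fh.write(MODULE_SET_MAGIC + "\n")
        fh.write("# provenance: " + json.dumps(dict(ms.provenance), sort_keys=True, default=str) + "\n")
        fh.write("feature_id\tmodule\n")
        for m in ms.modules:
            for g in sorted(m.members):
                fh.write(f"{g}\t{m.name}\n")
        for g in sorted(ms.unassigned):
            fh.write(f"{g}\t{UNASSIGNED_LABEL}\n")


def read_module_set(path: str | Path) -> ModuleSet:
    path = Path(path)
    with path.open() as fh:
        magic = fh.readline().rstrip("\n")
        if magic != MODULE_SET_MAGIC:
            raise FormatError(f"{path}: missing magic line {MODULE_SET_MAGIC!r}")
        provenance: dict[str, object] = {}
        members: dict[str, list[str]] = {}
        order: list[str] = []
        unassigned: set[str] = set()
        assigned_once: dict[str, str] = {}
        header_seen = False
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("# provenance:"):
                provenance = json.loads(line.split(":", 1)[1])
                continue
            if line.startswith("#"):
                continue
            if not header_seen:
                if line != "feature_id\tmodule":
                    raise FormatError(f"{path}:{lineno}: expected column header 'feature_id\\tmodule'")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            feature, module = parts
            if feature in assigned_once:
                raise IdentifierError(
                    f"{path}:{lineno}: feature {feature!r} assigned to both "
                    f"{assigned_once[feature]!r} and {module!r}"
                )
            assigned_once[feature] = module
            if module == UNASSIGNED_LABEL:
                unassigned.add(feature)
            else:
                if module not in members:
                    members[module] = []
                    order.append(module)
                members[module].append(feature)
    modules = tuple(GeneModule(name, frozenset(members[name])) for name in order)
    return ModuleSet(modules=modules, unassigned=frozenset(unassigned), provenance=provenance)


def apply_feature_mapping(ms: ModuleSet, mapping: Mapping[str, str]) -> ModuleSet:
    """Translate feature identifiers (e.g. probe set -> gene symbol).

    Features absent from the mapping are dropped; collisions (two probes
    mapping to one symbol inside a module) collapse to one member, matching
    set semantics.
    """
    modules = []
    for m in ms.modules:
        mapped = frozenset(mapping[g] for g in m.members if g in mapping)
        if mapped:
            modules.append(GeneModule(m.name, mapped))
    unassigned = frozenset(mapping[g] for g in ms.unassigned if g in mapping)
    assigned = set().union(*[m.members for m in modules]) if modules else set()
    return ModuleSet(tuple(modules), unassigned - assigned, dict(ms.provenance))


def read_feature_mapping(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Two-column mapping file: source id, target id."""
    mapping: dict[str, str] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            mapping[parts[0]] = parts[1]
    return mapping
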
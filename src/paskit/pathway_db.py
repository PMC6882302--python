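"""Pathway knowledge base with per-gene activator/repressor roles.

A pathway is a named gene set in which every member gene carries a discrete
activator/repressor role weight (ARR).  ARR encodes what the gene product
does *to* the pathway: +1 full activator, +0.5 weak activator, 0 neutral
member, -0.5 weak repressor, -1 full repressor.  The pathway activation
score (see :mod:`paskit.pas`) needs only membership and these role weights;
network topology is deliberately not modelled.

The on-disk dialect is a GMT-inspired TSV, one pathway per line::

    <main_pathway>\\t<branch>\\t<gene>:<arr>[\\t<gene>:<arr>]...

with ``arr`` written as one of ``-1, -0.5, 0, 0.5, 1`` and ``#`` starting a
comment line.  Standard GMT has no role weights, hence the dialect.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

from .errors import DegenerateInputError, DuplicateKeyError, FormatError

__all__ = [
    "ALLOWED_ARR",
    "GeneRole",
    "PathwayDef",
    "PathwayCollection",
    "parse_pathway_db",
    "write_pathway_db",
    "jaccard_similarity",
]

#: Permitted discrete ARR weights, from full repressor to full activator.
ALLOWED_ARR = (-1.0, -0.5, 0.0, 0.5, 1.0)

_ARR_REPR = {-1.0: "-1", -0.5: "-0.5", 0.0: "0", 0.5: "0.5", 1.0: "1"}


@dataclass(frozen=True)
class GeneRole:
    """One gene's membership in one pathway, with its role weight."""

    gene: str
    arr: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise FormatError("gene identifier must be non-empty")
        if self.arr not in ALLOWED_ARR:
            raise FormatError(
                f"ARR weight {self.arr!r} for gene {self.gene!r} is not one of "
                f"{ALLOWED_ARR}"
            )


@dataclass(frozen=True)
class PathwayDef:
    """A named pathway branch mapping member genes to ARR weights.

    ``branch`` may be the literal ``"main"`` for the parent pathway itself;
    the ``(main_pathway, branch)`` pair is the unique key within a
    collection.
    """

    main_pathway: str
    branch: str
    roles: tuple[GeneRole, ...]

    def __post_init__(self) -> None:
        if not self.roles:
            raise FormatError(
                f"pathway {self.main_pathway!r}/{self.branch!r} has no genes"
            )
        seen: set[str] = set()
        for role in self.roles:
            if role.gene in seen:
                raise DuplicateKeyError(
                    f"gene {role.gene!r} listed twice in pathway "
                    f"{self.main_pathway!r}/{self.branch!r}"
                )
            seen.add(role.gene)

    @property
    def key(self) -> tuple[str, str]:
        return (self.main_pathway, self.branch)

    @property
    def name(self) -> str:
        """Display name: ``"main (branch)"``, or just the main name."""
        if self.branch == "main":
            return self.main_pathway
        return f"{self.main_pathway} ({self.branch})"

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(r.gene for r in self.roles)

    def arr_map(self) -> dict[str, float]:
        return {r.gene: r.arr for r in self.roles}


class PathwayCollection:
    """Ordered set of :class:`PathwayDef` with unique ``(main, branch)`` keys."""

    def __init__(self, pathways: Iterable[PathwayDef]):
        self._pathways: list[PathwayDef] = list(pathways)
        self._by_key: dict[tuple[str, str], PathwayDef] = {}
        for pw in self._pathways:
            if pw.key in self._by_key:
                raise DuplicateKeyError(
                    f"duplicate pathway key {pw.key!r} in collection"
                )
            self._by_key[pw.key] = pw

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self) -> Iterator[PathwayDef]:
        return iter(self._pathways)

    def __contains__(self, key: object) -> bool:
        if isinstance(key, tuple):
            return key in self._by_key
        return any(pw.name == key for pw in self._pathways)

    def __getitem__(self, key: tuple[str, str] | str) -> PathwayDef:
        if isinstance(key, tuple):
            return self._by_key[key]
        for pw in self._pathways:
            if pw.name == key:
                return pw
        raise KeyError(key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCollection):
            return NotImplemented
        return self._pathways == other._pathways

    @property
    def pathways(self) -> list[PathwayDef]:
        return list(self._pathways)

    @property
    def names(self) -> list[str]:
        return [pw.name for pw in self._pathways]

    @property
    def universe(self) -> frozenset[str]:
        """All gene identifiers appearing in any member pathway."""
        genes: set[str] = set()
        for pw in self._pathways:
            genes.update(pw.genes)
        return frozenset(genes)


def parse_pathway_db(path) -> PathwayCollection:
    """Read a pathway database file in the gene:arr TSV dialect.

    Raises :class:`FormatError` naming the offending line for malformed
    records or ARR values outside the five-level set, and
    :class:`DuplicateKeyError` for repeated ``(main, branch)`` keys.
    Pathway order in the file is preserved.
    """
    pathways: list[PathwayDef] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: expected at least 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            main, branch, *tokens = fields
            roles = []
            for token in tokens:
                gene, sep, arr_text = token.rpartition(":")
                if not sep or not gene or not arr_text:
                    raise FormatError(
                        f"line {lineno}: malformed gene:arr token {token!r}"
                    )
                try:
                    arr = float(arr_text)
                except ValueError as exc:
                    raise FormatError(
                        f"line {lineno}: ARR value {arr_text!r} is not numeric"
                    ) from exc
                if arr not in ALLOWED_ARR:
                    raise FormatError(
                        f"line {lineno}: ARR value {arr_text!r} not in "
                        f"{_ARR_REPR.values()}"
                    )
                roles.append(GeneRole(gene, arr))
            try:
                pathways.append(PathwayDef(main, branch, tuple(roles)))
            except DuplicateKeyError as exc:
                raise DuplicateKeyError(f"line {lineno}: {exc}") from exc
    return PathwayCollection(pathways)


def write_pathway_db(collection: PathwayCollection, path) -> None:
    """Write a collection in the same dialect :func:`parse_pathway_db` reads."""
    with open(path, "w", encoding="utf-8") as handle:
        for pw in collection:
            tokens = [f"{r.gene}:{_ARR_REPR[r.arr]}" for r in pw.roles]
            handle.write("\t".join([pw.main_pathway, pw.branch, *tokens]) + "\n")


def jaccard_similarity(a: PathwayDef, b: PathwayDef) -> float:
    """Jaccard coefficient between two pathways' gene sets.

    |genes(a) ∩ genes(b)| / |genes(a) ∪ genes(b)|, in [0, 1] and symmetric.
    Role weights are ignored: similarity is about shared membership.
    """
    ga, gb = a.genes, b.genes
    if not ga or not gb:
        raise DegenerateInputError("Jaccard similarity of an empty pathway")
    return len(ga & gb) / len(ga | gb)
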
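"""Taxonomic tree, lineage/LCA queries and the contaminant-genus list.

The tree is the NCBI-style forest of taxids rooted at taxid 1 (whose parent
is itself).  Two on-disk dialects are read: the NCBI dump dialect of
``nodes.dmp``/``names.dmp`` (``<TAB>|<TAB>``-separated) and a plain
3-column TSV.  Only the rank string ``"genus"`` is interpreted specially;
all other rank labels are free-form.

Contaminant genera are matched by scientific name (case-sensitive), with two
statuses: ``flagged`` (the genus includes species potentially associated with
the host — inspect, do not necessarily discard) and ``blacklisted`` (known
reagent/kitome contaminant — discard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Optional, Tuple, Union

__all__ = [
    "TaxonomyTree",
    "TaxonomyError",
    "ContaminantList",
    "load_taxonomy",
    "load_contaminants",
    "CONTAMINANT_STATUSES",
]

ROOT_TAXID = 1
CONTAMINANT_STATUSES = ("flagged", "blacklisted")


class TaxonomyError(ValueError):
    pass


@dataclass
class TaxonomyTree:
    """taxid -> (parent, rank, name) forest rooted at taxid 1."""

    parent: Dict[int, int] = field(default_factory=dict)
    rank: Dict[int, str] = field(default_factory=dict)
    name: Dict[int, str] = field(default_factory=dict)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def _require(self, taxid: int) -> None:
        if taxid not in self.parent:
            raise TaxonomyError(f"unknown taxid {taxid}")

    def add_node(self, taxid: int, parent: int, rank: str, name: str = "") -> None:
        self.parent[taxid] = parent
        self.rank[taxid] = rank
        if name:
            self.name[taxid] = name

    def validate(self) -> None:
        """Check every parent exists and every chain reaches the root (no cycles)."""
        if ROOT_TAXID not in self.parent or self.parent[ROOT_TAXID] != ROOT_TAXID:
            raise TaxonomyError("taxonomy must contain root taxid 1 with parent 1")
        for taxid, parent in self.parent.items():
            if parent not in self.parent:
                raise TaxonomyError(f"taxid {taxid} has unknown parent {parent}")
        for taxid in self.parent:
            seen = set()
            node = taxid
            while node != ROOT_TAXID:
                if node in seen:
                    raise TaxonomyError(f"cycle detected at taxid {node}")
                seen.add(node)
                node = self.parent[node]

    def lineage(self, taxid: int) -> list[int]:
        """Root-to-node path, root first, ``taxid`` last."""
        self._require(taxid)
        path = [taxid]
        while path[-1] != ROOT_TAXID:
            path.append(self.parent[path[-1]])
        path.reverse()
        return path

    def depth(self, taxid: int) -> int:
        return len(self.lineage(taxid)) - 1

    def lca(self, a: int, b: int) -> int:
        """Lowest common ancestor: the deepest node on both root paths."""
        self._require(a)
        self._require(b)
        ancestors_a = set(self.lineage(a))
        node = b
        while node not in ancestors_a:
            node = self.parent[node]
        return node

    def lca_of(self, taxids) -> int:
        """Fold :meth:`lca` over a non-empty iterable of taxids."""
        it = iter(taxids)
        try:
            acc = next(it)
        except StopIteration:
            raise TaxonomyError("lca_of requires at least one taxid") from None
        self._require(acc)
        for t in it:
            acc = self.lca(acc, t)
        return acc

    def genus_of(self, taxid: int) -> Optional[int]:
        """Nearest ancestor-or-self with rank ``genus``; None if absent."""
        self._require(taxid)
        node = taxid
        while True:
            if self.rank.get(node) == "genus":
                return node
            if node == ROOT_TAXID:
                return None
            node = self.parent[node]

    def is_host_lineage(self, taxid: int, host: int) -> bool:
        """True iff ``taxid`` equals, is an ancestor of, or descends from ``host``."""
        self._require(taxid)
        self._require(host)
        return taxid in set(self.lineage(host)) or host in set(self.lineage(taxid))


def _iter_dump_rows(path: Path) -> Iterator[Tuple[int, list[str]]]:
    """Yield (lineno, fields) for either dump dialect or plain TSV."""
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if "\t|" in line:
                fields = [f.strip() for f in line.rstrip("\t|").split("\t|\t")]
            else:
                fields = line.split("\t")
            yield lineno, fields


def load_taxonomy(
    nodes_path: Union[str, Path],
    names_path: Optional[Union[str, Path]] = None,
) -> TaxonomyTree:
    """Load a taxonomy from NCBI-dump or plain-TSV node/name tables.

    ``nodes`` rows are ``taxid, parent, rank[, ...]``; ``names`` rows are
    ``taxid, name[, unique name, name class]`` where, in the NCBI dialect,
    only rows of class ``scientific name`` are kept.  A plain 3-column nodes
    TSV may also carry the name in a 4th column, making ``names_path``
    optional.
    """
    tree = TaxonomyTree()
    for lineno, fields in _iter_dump_rows(Path(nodes_path)):
        if len(fields) < 3:
            raise TaxonomyError(
                f"{nodes_path}: line {lineno}: expected taxid, parent, rank"
            )
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxonomyError(f"{nodes_path}: line {lineno}: {exc}") from exc
        if taxid in tree.parent:
            raise TaxonomyError(f"{nodes_path}: line {lineno}: duplicate taxid {taxid}")
        name = fields[3] if len(fields) > 3 and not _looks_like_name_class(fields) else ""
        tree.add_node(taxid, parent, fields[2], name)
    if names_path is not None:
        for lineno, fields in _iter_dump_rows(Path(names_path)):
            if len(fields) < 2:
                continue
            try:
                taxid = int(fields[0])
            except ValueError as exc:
                raise TaxonomyError(f"{names_path}: line {lineno}: {exc}") from exc
            if len(fields) >= 4 and fields[3] != "scientific name":
                continue
            if taxid in tree.parent:
                tree.name[taxid] = fields[1]
    tree.validate()
    return tree


def _looks_like_name_class(fields: list[str]) -> bool:
    # NCBI nodes.dmp carries embl codes etc. after rank; a plain TSV that
    # includes a name puts it in column 4.  Heuristic: NCBI nodes.dmp has
    # >= 13 fields.
    return len(fields) >= 13


@dataclass
class ContaminantList:
    """Genus name -> status in {flagged, blacklisted}; absent genera are clean."""

    entries: Dict[str, str] = field(default_factory=dict)

    def status_of(self, genus_name: Optional[str]) -> Optional[str]:
        if genus_name is None:
            return None
        return self.entries.get(genus_name)

    def __len__(self) -> int:
        return len(self.entries)


def load_contaminants(path: Union[str, Path]) -> ContaminantList:
    """Read a two-column ``genus<TAB>status`` TSV.

    Conflicting duplicate rows are an error; agreeing duplicates are allowed.
    """
    entries: Dict[str, str] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise TaxonomyError(f"{path}: line {lineno}: expected genus<TAB>status")
            genus, status = fields[0].strip(), fields[1].strip()
            if genus == "genus" and status == "status":
                continue  # header
            if status not in CONTAMINANT_STATUSES:
                raise TaxonomyError(
                    f"{path}: line {lineno}: status {status!r} not in {CONTAMINANT_STATUSES}"
                )
            if genus in entries and entries[genus] != status:
                raise TaxonomyError(
                    f"{path}: line {lineno}: genus {genus!r} listed with conflicting statuses"
                )
            entries[genus] = status
    return ContaminantList(entries)


def default_contaminants_path() -> Path:
    """Path of the curated default contaminant-genus list shipped as data."""
    return Path(__file__).parent / "data" / "contaminants.tsv"
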
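"""Gene-set collections as binary gene x group membership matrices.

Annotation sources (GMT gene-set files, GO annotation GAF files) are read
into a single structure, :class:`AnnotationMatrix`, that every other module
consumes: a boolean membership matrix over an ordered gene universe.  The
universe policy mirrors common benchmark practice: the universe is the
supplied gene list (e.g. the genes on a platform), and genes with no
annotations stay in the universe as negatives unless explicitly dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneUniverse",
    "AnnotationMatrix",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_gaf",
    "filter_by_size",
]


class GmtParseError(ValueError):
    """Raised for malformed GMT/GAF input, naming the offending line."""


@dataclass(frozen=True)
class GeneUniverse:
    """An ordered collection of unique gene identifiers.

    Order is stable and reproducible: lexicographic when the universe is
    derived from a file, or exactly the supplied order when given one.
    """

    gene_ids: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if len(self.gene_ids) == 0:
            raise ValueError("empty gene universe")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.gene_ids)})

    @classmethod
    def from_iterable(cls, genes: Iterable[str], *, sort: bool = True) -> "GeneUniverse":
        genes = list(dict.fromkeys(genes))
        if sort:
            genes = sorted(genes)
        return cls(tuple(genes))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def __iter__(self):
        return iter(self.gene_ids)

    def index(self, gene: str) -> int:
        return self._index[gene]

    def indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._index[g] for g in genes], dtype=np.intp)


@dataclass
class AnnotationMatrix:
    """Binary gene x function-group membership.

    ``membership[i, j]`` is True iff gene i belongs to group j.  Column sums
    are the in-group sizes (``Num_in``); their complements against the
    universe size are ``Num_out``.
    """

    universe: GeneUniverse
    group_ids: tuple[str, ...]
    membership: np.ndarray  # (n_genes, n_groups) boolean

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != (len(self.universe), len(self.group_ids)):
            raise ValueError(
                f"membership shape {self.membership.shape} does not match "
                f"{len(self.universe)} genes x {len(self.group_ids)} groups"
            )
        if len(set(self.group_ids)) != len(self.group_ids):
            raise ValueError("duplicate group ids")

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    @property
    def group_sizes(self) -> np.ndarray:
        """Num_in per group: number of genes inside each group."""
        return self.membership.sum(axis=0)

    @property
    def complement_sizes(self) -> np.ndarray:
        """Num_out per group: number of universe genes outside each group."""
        return self.n_genes - self.group_sizes

    @property
    def annotations_per_gene(self) -> np.ndarray:
        return self.membership.sum(axis=1)

    def group_members(self, group_id: str) -> list[str]:
        j = self.group_ids.index(group_id)
        return [self.universe.gene_ids[i] for i in np.flatnonzero(self.membership[:, j])]

    def select_groups(self, keep: Sequence[str] | np.ndarray) -> "AnnotationMatrix":
        """Return a copy restricted to the given group ids (or boolean mask)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {g: j for j, g in enumerate(self.group_ids)}
            idx = np.array([pos[g] for g in keep], dtype=np.intp)
        return AnnotationMatrix(
            universe=self.universe,
            group_ids=tuple(self.group_ids[j] for j in idx),
            membership=self.membership[:, idx],
        )

    def drop_unannotated(self) -> "AnnotationMatrix":
        """Restrict the universe to genes with at least one annotation."""
        keep = self.annotations_per_gene > 0
        if not keep.any():
            raise ValueError("no annotated genes to keep")
        uni = GeneUniverse(tuple(np.array(self.universe.gene_ids)[keep]))
        return AnnotationMatrix(uni, self.group_ids, self.membership[keep])


def _build_matrix(
    sets: dict[str, list[str]],
    universe: GeneUniverse | None,
    *,
    case_fold: bool = False,
) -> AnnotationMatrix:
    if case_fold:
        sets = {name: [g.casefold() for g in genes] for name, genes in sets.items()}
        if universe is not None:
            universe = GeneUniverse(tuple(g.casefold() for g in universe.gene_ids))
    if universe is None:
        universe = GeneUniverse.from_iterable(
            g for genes in sets.values() for g in genes
        )
        dropped = 0
    else:
        known = set(universe.gene_ids)
        dropped = sum(1 for genes in sets.values() for g in genes if g not in known)
        if dropped:
            logger.info("dropped %d memberships for genes outside the universe", dropped)
        sets = {
            name: [g for g in genes if g in known] for name, genes in sets.items()
        }
    membership = np.zeros((len(universe), len(sets)), dtype=bool)
    for j, genes in enumerate(sets.values()):
        if genes:
            membership[universe.indices(genes), j] = True
    return AnnotationMatrix(universe, tuple(sets.keys()), membership)


def read_gmt(
    path: str | Path,
    universe: GeneUniverse | None = None,
    *,
    case_fold: bool = False,
) -> AnnotationMatrix:
    """Read a Broad-dialect GMT file (name, description, genes...).

    Without a supplied universe, the universe is the sorted union of all
    genes in the file.  With one, genes outside it are dropped (count
    logged) and genes never annotated remain as all-negative rows.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return _build_matrix(sets, universe, case_fold=case_fold)


def write_gmt(a: AnnotationMatrix, path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    """Write an AnnotationMatrix as GMT; empty groups are kept as empty lines."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for j, name in enumerate(a.group_ids):
            genes = [a.universe.gene_ids[i] for i in np.flatnonzero(a.membership[:, j])]
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _obo_ancestors(obo_path: str | Path) -> dict[str, set[str]]:
    """Transitive is_a/part_of ancestors per term from an OBO 1.2 file."""
    import obonet

    graph = obonet.read_obo(str(obo_path))
    # obonet edges point child -> parent, keyed by relation
    parents: dict[str, set[str]] = {}
    for child, parent, rel in graph.edges(keys=True):
        if rel in ("is_a", "part_of"):
            parents.setdefault(child, set()).add(parent)
    cache: dict[str, set[str]] = {}

    def walk(term: str) -> set[str]:
        if term in cache:
            return cache[term]
        cache[term] = set()  # guard against cycles
        out: set[str] = set()
        for p in parents.get(term, ()):
            out.add(p)
            out |= walk(p)
        cache[term] = out
        return out

    return {t: walk(t) for t in graph.nodes}


def read_gaf(
    path: str | Path,
    obo: str | Path | None = None,
    *,
    propagate: bool = False,
    universe: GeneUniverse | None = None,
    aspects: Sequence[str] | None = None,
    id_column: int = 2,
) -> AnnotationMatrix:
    """Read GAF 2.x annotations into a gene x GO-term membership matrix.

    NOT-qualified rows are excluded.  With ``propagate``, each annotation is
    propagated to all is_a/part_of ancestors from the OBO file; terms absent
    from the ontology are kept unpropagated with a warning.  ``aspects``
    restricts to GO aspects (subset of {"P", "F", "C"}); default all.
    ``id_column`` selects the gene identifier column (1 = DB object id,
    2 = symbol; GAF columns are 0-based here).
    """
    if propagate and obo is None:
        raise ValueError("propagate=True requires an OBO file")
    ancestors = _obo_ancestors(obo) if propagate else {}
    aspect_set = set(aspects) if aspects is not None else None
    pairs: set[tuple[str, str]] = set()
    unknown_terms: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 15:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=15 tab-separated GAF fields"
                )
            qualifier = fields[3]
            if "NOT" in qualifier.split("|"):
                continue
            if aspect_set is not None and fields[8] not in aspect_set:
                continue
            gene = fields[id_column]
            term = fields[4]
            pairs.add((gene, term))
            if propagate:
                anc = ancestors.get(term)
                if anc is None:
                    unknown_terms.add(term)
                else:
                    pairs.update((gene, t) for t in anc)
    if unknown_terms:
        logger.warning(
            "%d terms not found in the ontology were kept unpropagated: %s",
            len(unknown_terms),
            sorted(unknown_terms)[:5],
        )
    terms = sorted({t for _, t in pairs})
    sets = {t: [g for g, t2 in pairs if t2 == t] for t in terms}
    return _build_matrix(sets, universe)


def filter_by_size(
    a: AnnotationMatrix, min_size: int = 20, max_size: int = 1000
) -> AnnotationMatrix:
    """Keep groups with min_size <= Num_in <= max_size; universe unchanged.

    The 20-1000 defaults are the conventional benchmark band for GO groups:
    large enough to learn from, small enough to be specific.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    sizes = a.group_sizes
    keep = (sizes >= min_size) & (sizes <= max_size)
    if not keep.any():
        logger.warning("size filter [%d, %d] removed every group", min_size, max_size)
    return a.select_groups(keep)
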
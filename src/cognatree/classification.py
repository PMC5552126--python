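"""Reference taxonomies: clade lookup, constraints, calibrations, geography.

A classification is a rooted labelled tree (Glottolog-style) supplied as a
Newick file — node labels are clade/language names, an optional square-
bracket comment on a node is its stable code — plus an optional CSV sidecar
of per-leaf metadata (id, iso, latitude, longitude, macroarea).  From it we
derive language selections (by family and/or macroarea), monophyly
constraints, calibration clades and leaf locations.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field

import dendropy

from .errors import CladeLookupError, DataError, ModelError
from .phylo import Node, PhyloTree


@dataclass
class CNode:
    """One node of the classification tree (not necessarily binary)."""

    name: str | None
    code: str
    children: list["CNode"] = field(default_factory=list)
    parent: "CNode | None" = None
    # leaf metadata
    iso: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    macroarea: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["CNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class MonophylyConstraint:
    """A leaf set required to be a clade in every sampled tree."""

    label: str
    leaves: frozenset
    parent: "MonophylyConstraint | None" = None

    def __len__(self) -> int:
        return len(self.leaves)


class Classification:
    """Rooted labelled taxonomy with name/code lookup and leaf geography."""

    def __init__(self, root: CNode):
        self.root = root
        self.nodes: list[CNode] = []

        def walk(n: CNode) -> None:
            self.nodes.append(n)
            for c in n.children:
                c.parent = n
                walk(c)

        walk(root)
        self.leaf_nodes = [n for n in self.nodes if n.is_leaf]
        ids = [n.name for n in self.leaf_nodes]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate leaf IDs in classification")
        self.by_code: dict[str, CNode] = {}
        self.by_name: dict[str, list[CNode]] = {}
        for n in self.nodes:
            if n.code in self.by_code:
                raise DataError(f"duplicate classification code {n.code!r}")
            self.by_code[n.code] = n
            if n.name:
                self.by_name.setdefault(n.name.lower(), []).append(n)
        areas = {n.macroarea for n in self.leaf_nodes if n.macroarea}
        if len(areas) > 6:
            raise DataError(f"more than six macroareas in sidecar: {sorted(areas)}")

    @property
    def leaf_ids(self) -> list[str]:
        return [n.name for n in self.leaf_nodes]


def _clean_code(comment: str) -> str:
    c = comment.strip().lstrip("&")
    if c.lower().startswith("code="):
        c = c[5:]
    return c.strip()


def load_classification(stream, metadata_stream=None) -> Classification:
    """Load a classification from Newick text plus an optional CSV sidecar.

    Sidecar columns: ``id, iso, latitude, longitude, macroarea`` (header
    required; trailing columns optional per row).
    """
    text = stream.read() if hasattr(stream, "read") else stream
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as e:  # dendropy raises several parser error types
        raise DataError(f"malformed Newick: {e}") from e

    counter = [0]

    def convert(dnode) -> CNode:
        if dnode.taxon is not None:
            name = dnode.taxon.label
        else:
            name = dnode.label
        if dnode.comments:
            code = _clean_code(dnode.comments[0])
        else:
            counter[0] += 1
            code = f"node{counter[0]}"
        node = CNode(name=name, code=code)
        for child in dnode.child_nodes():
            node.children.append(convert(child))
        return node

    cls = Classification(convert(dtree.seed_node))

    if metadata_stream is not None:
        meta_text = (metadata_stream.read()
                     if hasattr(metadata_stream, "read") else metadata_stream)
        by_id = {n.name: n for n in cls.leaf_nodes}
        for row in csv.DictReader(io.StringIO(meta_text)):
            row = {k.strip().lower(): (v.strip() if v else "")
                   for k, v in row.items()}
            leaf = by_id.get(row.get("id", ""))
            if leaf is None:
                warnings.warn(f"sidecar row for unknown leaf {row.get('id')!r}")
                continue
            leaf.iso = row.get("iso") or None
            if row.get("latitude"):
                lat = float(row["latitude"])
                if not -90 <= lat <= 90:
                    raise DataError(f"latitude out of range: {lat}")
                leaf.latitude = lat
            if row.get("longitude"):
                lon = float(row["longitude"])
                if not -180 <= lon <= 180:
                    raise DataError(f"longitude out of range: {lon}")
                leaf.longitude = lon
            leaf.macroarea = row.get("macroarea") or None
        # re-validate the macroarea budget after attaching metadata
        areas = {n.macroarea for n in cls.leaf_nodes if n.macroarea}
        if len(areas) > 6:
            raise DataError(f"more than six macroareas: {sorted(areas)}")
    return cls


def resolve_clade(cls: Classification, name_or_code: str) -> set[str]:
    """Leaf IDs under the named clade; names match case-insensitively,
    codes exactly.  Ambiguous names tell the caller to use the code."""
    node = cls.by_code.get(name_or_code)
    if node is None:
        hits = cls.by_name.get(name_or_code.lower(), [])
        if len(hits) > 1:
            codes = ", ".join(h.code for h in hits)
            raise CladeLookupError(
                f"name {name_or_code!r} is shared by {len(hits)} clades; "
                f"refer to one by code ({codes})")
        if not hits:
            near = [n for n in cls.by_name
                    if name_or_code.lower() in n or n in name_or_code.lower()]
            hint = f" (near misses: {', '.join(sorted(near)[:5])})" if near else ""
            raise CladeLookupError(f"unknown clade {name_or_code!r}{hint}")
        node = hits[0]
    return {leaf.name for leaf in node.leaves()}


def _match_scheme(cls: Classification, data_languages) -> dict[str, CNode]:
    """Map data-language identifiers onto classification leaves.

    Tries, in order: exact leaf ID, ISO code, classification code; the
    first scheme matching at least one data language is used for all.
    """
    data_languages = list(data_languages)
    schemes = [
        {n.name: n for n in cls.leaf_nodes},
        {n.iso: n for n in cls.leaf_nodes if n.iso},
        {n.code: n for n in cls.leaf_nodes},
    ]
    for table in schemes:
        mapping = {l: table[l] for l in data_languages if l in table}
        if mapping:
            return mapping
    return {}


def select_languages(cls: Classification, families: list[str],
                     macroareas: list[str], exclusions: list[str],
                     data_languages) -> set[str]:
    """Family/macroarea/exclusion filtering of the data's language set."""
    from .errors import SelectionError

    data_languages = list(data_languages)
    mapping = _match_scheme(cls, data_languages)
    selected = set(data_languages)
    if families:
        fam_ids: set[str] = set()
        for fam in families:
            fam_ids |= resolve_clade(cls, fam)
        selected &= {l for l in selected
                     if l in mapping and mapping[l].name in fam_ids}
    if macroareas:
        wanted = {m.lower() for m in macroareas}
        selected &= {l for l in selected
                     if l in mapping and mapping[l].macroarea
                     and mapping[l].macroarea.lower() in wanted}
    selected -= set(exclusions)
    if not selected:
        raise SelectionError(
            "language selection is empty (families="
            f"{families}, macroareas={macroareas}, exclusions={exclusions})")
    return selected


def monophyly_constraints(cls: Classification,
                          languages) -> list[MonophylyConstraint]:
    """Constraints induced by restricting the classification to *languages*.

    Unary internal nodes are suppressed; every surviving internal node with
    at least two leaf descendants and a proper-subset leaf set becomes a
    constraint.  If any data language is absent from the classification the
    feature is disabled entirely (empty list) with a warning.
    """
    languages = list(languages)
    mapping = _match_scheme(cls, languages)
    missing = [l for l in languages if l not in mapping]
    if missing:
        warnings.warn(
            "monophyly constraints disabled: languages not in the "
            f"classification: {sorted(missing)[:5]}")
        return []
    leaf_to_lang = {id(v): l for l, v in mapping.items()}
    keep = {id(v) for v in mapping.values()}
    all_langs = frozenset(languages)

    constraints: list[MonophylyConstraint] = []

    def restrict(node: CNode) -> frozenset:
        if node.is_leaf:
            return (frozenset([leaf_to_lang[id(node)]])
                    if id(node) in keep else frozenset())
        sets = [restrict(c) for c in node.children]
        nonempty = [s for s in sets if s]
        merged = frozenset().union(*sets) if sets else frozenset()
        # a node surviving with >=2 children after restriction is a clade
        if (len(nonempty) >= 2 and len(merged) >= 2
                and merged != all_langs):
            constraints.append(MonophylyConstraint(
                node.name or node.code, merged))
        return merged

    restrict(cls.root)
    # link nesting (parent = smallest strict superset)
    by_size = sorted(constraints, key=len)
    for i, c in enumerate(by_size):
        for d in by_size[i + 1:]:
            if c.leaves < d.leaves:
                c.parent = d
                break
    return constraints


def locations(cls: Classification, languages,
              override_csv: str | None = None) -> dict[str, tuple[float, float]]:
    """Per-language (latitude, longitude); override CSV wins per language."""
    mapping = _match_scheme(cls, languages)
    out: dict[str, tuple[float, float]] = {}
    for lang in languages:
        leaf = mapping.get(lang)
        if leaf is not None and leaf.latitude is not None and leaf.longitude is not None:
            out[lang] = (leaf.latitude, leaf.longitude)
    if override_csv:
        for row in csv.DictReader(io.StringIO(override_csv)):
            row = {k.strip().lower(): (v.strip() if v else "")
                   for k, v in row.items()}
            lang = row.get("id", "")
            if lang in set(languages) and row.get("latitude") and row.get("longitude"):
                out[lang] = (float(row["latitude"]), float(row["longitude"]))
    dropped = [l for l in languages if l not in out]
    if dropped:
        warnings.warn(f"no location for languages: {sorted(dropped)[:5]}")
    return out


# --------------------------------------------------------------------------
# fixed analysis trees
# --------------------------------------------------------------------------

def load_phylotree(newick_text: str) -> PhyloTree:
    """Parse an ultrametric Newick tree into a height-based PhyloTree."""
    try:
        dtree = dendropy.Tree.get(data=newick_text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as e:
        raise DataError(f"malformed Newick: {e}") from e

    depths: dict[int, float] = {}

    def depth_walk(dnode, d: float) -> None:
        depths[id(dnode)] = d
        for c in dnode.child_nodes():
            depth_walk(c, d + (c.edge.length or 0.0))

    depth_walk(dtree.seed_node, 0.0)
    leaf_depths = [depths[id(n)] for n in dtree.leaf_node_iter()]
    total = max(leaf_depths)
    if total <= 0:
        raise DataError("tree has no branch lengths")
    if max(leaf_depths) - min(leaf_depths) > 1e-6 * total:
        raise DataError("fixed analysis tree must be ultrametric "
                        "(all leaves equidistant from the root)")

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label, max(total - depths[id(dnode)], 0.0))
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    _suppress_unary(root)
    for leaf in PhyloTree(root).leaves:
        leaf.height = 0.0
    return PhyloTree(root)


def _suppress_unary(node: Node) -> None:
    for c in list(node.children):
        _suppress_unary(c)
    if len(node.children) == 1:
        child = node.children[0]
        node.label = child.label
        node.height = child.height
        node.children = child.children
        for gc in node.children:
            gc.parent = node


def prune_fixed_tree(tree: PhyloTree, data_languages) -> PhyloTree:
    """Drop leaves absent from the data, suppressing unary nodes.

    Surviving nodes keep their original heights, so leaf-to-leaf patristic
    distances among survivors are unchanged.
    """
    keep = set(data_languages)
    tree = tree.copy()

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            return node if node.label in keep else None
        kept = [prune(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    root = prune(tree.root)
    if root is None or root.is_leaf:
        raise ModelError("fewer than 2 leaves survive pruning to the data")
    root.parent = None
    out = PhyloTree(root)
    out.validate()
    return out
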
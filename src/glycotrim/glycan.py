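"""Rooted-tree model of oligomannosidic N-glycans.

The unprocessed N-glycan transferred in the ER, Glc3Man9GlcNAc2, is a rooted
tree: a chitobiose core (GlcNAc-β1,4-GlcNAc) carrying a β1,4 mannose from
which three mannose branches extend.  The α1,3 arm is the A-branch
(Man-α1,2-Man-α1,2 capped by Glcα1,3-Glcα1,3-Glcα1,2); the α1,6 arm is a
branch point carrying the B-branch (Man-α1,2 on an α1,3 mannose) and the
C-branch (Man-α1,2 on an α1,6 mannose).  Every structure handled here is a
sub/super-structure of this topology produced by processing-enzyme rules.

Mass spectrometry cannot distinguish Glc from Man, so trees collapse to
Hex/HexNAc *compositions* for identification and quantification; the tree
level is what the enzyme rules operate on and what disambiguates isobaric
structures such as Man8GlcNAc2 and Glc1Man7GlcNAc2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator

from . import masses

SUGARS = ("Glc", "Man", "GlcNAc")
#: child ordering used by the canonical structure-string form
LINKAGES = ("a1-2", "a1-3", "a1-6", "b1-4")


class GlycanError(ValueError):
    """Malformed glycan structure, name or string."""


@dataclass(frozen=True)
class GlycanComposition:
    """Counts of the four monosaccharide classes seen by MS."""

    hexnac: int = 0
    hex: int = 0
    dhex: int = 0
    pent: int = 0

    def __post_init__(self) -> None:
        for f in ("hexnac", "hex", "dhex", "pent"):
            v = getattr(self, f)
            if not isinstance(v, int) or v < 0:
                raise GlycanError(f"composition count {f}={v!r} must be a non-negative int")

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac,
            self.hex + other.hex,
            self.dhex + other.dhex,
            self.pent + other.pent,
        )

    @property
    def total(self) -> int:
        return self.hexnac + self.hex + self.dhex + self.pent

    def mass(self, released: bool = False) -> float:
        """Neutral monoisotopic mass of the glycan moiety.

        With ``released`` set, one water is added: the free reducing glycan
        as obtained after PNGase release, rather than the conjugated form.
        """
        m = (
            self.hex * masses.HEX
            + self.hexnac * masses.HEXNAC
            + self.dhex * masses.DHEX
            + self.pent * masses.PENT
        )
        return m + masses.WATER if released else m

    @property
    def label(self) -> str:
        """Display form matching glycoproteomics row labels (e.g. Hex9HexNAc2)."""
        parts = []
        if self.hex:
            parts.append(f"Hex{self.hex}")
        if self.hexnac:
            parts.append(f"HexNAc{self.hexnac}")
        if self.dhex:
            parts.append(f"dHex{self.dhex}")
        if self.pent:
            parts.append(f"Pent{self.pent}")
        return "".join(parts) or "Hex0HexNAc0"

    @classmethod
    def from_label(cls, label: str) -> "GlycanComposition":
        m = re.fullmatch(
            r"(?:Hex(\d+))?(?:HexNAc(\d+))?(?:dHex(\d+))?(?:Pent(\d+))?", label
        )
        if m is None or not any(m.groups()):
            raise GlycanError(f"unparseable composition label: {label!r}")
        g = [int(x) if x else 0 for x in m.groups()]
        return cls(hexnac=g[1], hex=g[0], dhex=g[2], pent=g[3])

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class GlycanResidue:
    residue_id: int
    sugar: str
    linkage: str | None  # None only for the reducing-end GlcNAc
    branch: str  # core | A | B | C | cap
    parent: int | None  # None only for the reducing-end GlcNAc

    def __post_init__(self) -> None:
        if self.sugar not in SUGARS:
            raise GlycanError(f"unknown sugar {self.sugar!r}")
        if self.linkage is not None and self.linkage not in LINKAGES:
            raise GlycanError(f"unknown linkage {self.linkage!r}")
        if (self.linkage is None) != (self.parent is None):
            raise GlycanError("linkage and parent must be absent together (root only)")


class GlycanTree:
    """A rooted glycan tree plus the rule provenance that produced it.

    Equality and hashing go through the canonical structure string
    (:func:`format_structure`), i.e. two trees are equal iff they are
    isomorphic as (sugar, linkage)-labelled rooted trees.  Branch labels are
    positional annotations fixed by the canonical topology, not part of
    identity.
    """

    def __init__(self, residues: dict[int, GlycanResidue], provenance: tuple[str, ...] = ()):
        self._residues = dict(residues)
        self.provenance = tuple(provenance)
        roots = [r.residue_id for r in self._residues.values() if r.parent is None]
        if len(roots) != 1:
            raise GlycanError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._children: dict[int, list[int]] = {rid: [] for rid in self._residues}
        for r in self._residues.values():
            if r.parent is not None:
                if r.parent not in self._residues:
                    raise GlycanError(f"residue {r.residue_id} has unknown parent {r.parent}")
                self._children[r.parent].append(r.residue_id)
        for rid, kids in self._children.items():
            links = [self._residues[k].linkage for k in kids]
            if len(links) != len(set(links)):
                raise GlycanError(f"residue {rid} has two children on the same linkage")
        # connectivity: everything reachable from the root (also rejects cycles)
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            seen.add(n)
            stack.extend(self._children[n])
        if seen != set(self._residues):
            raise GlycanError("tree is not connected from the root")

    # -- structure queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self._residues)

    def __iter__(self) -> Iterator[GlycanResidue]:
        return iter(self._residues.values())

    def residue(self, rid: int) -> GlycanResidue:
        return self._residues[rid]

    def children(self, rid: int) -> list[GlycanResidue]:
        return [self._residues[k] for k in self._children[rid]]

    def is_terminal(self, rid: int) -> bool:
        return not self._children[rid]

    def terminal_residues(self) -> list[GlycanResidue]:
        return [r for r in self if self.is_terminal(r.residue_id)]

    def find(self, sugar: str | None = None, linkage: str | None = None,
             branch: str | None = None, terminal: bool | None = None) -> list[GlycanResidue]:
        out = []
        for r in self:
            if sugar is not None and r.sugar != sugar:
                continue
            if linkage is not None and r.linkage != linkage:
                continue
            if branch is not None and r.branch != branch:
                continue
            if terminal is not None and self.is_terminal(r.residue_id) != terminal:
                continue
            out.append(r)
        return out

    def depth(self, rid: int) -> int:
        d = 0
        r = self._residues[rid]
        while r.parent is not None:
            d += 1
            r = self._residues[r.parent]
        return d

    def a_tip(self) -> GlycanResidue | None:
        """The distal-most A-branch mannose of the *intact* A-branch.

        Returns None when the A-branch has been trimmed below three
        mannoses, in which case UGGT has lost its acceptor site.
        """
        a_mans = [r for r in self.find(sugar="Man", branch="A")]
        if len(a_mans) != 3:
            return None
        return max(a_mans, key=lambda r: self.depth(r.residue_id))

    @property
    def os9_signal_exposed(self) -> bool:
        """True iff the C-branch α1,6-mannose (the OS9 degradation signal) is terminal."""
        stems = self.find(sugar="Man", linkage="a1-6", branch="C")
        return any(self.is_terminal(r.residue_id) for r in stems)

    # -- derived values ----------------------------------------------------

    def composition(self) -> GlycanComposition:
        """Collapse the tree to MS-visible counts (Glc and Man both count as Hex)."""
        hexnac = sum(1 for r in self if r.sugar == "GlcNAc")
        hexose = sum(1 for r in self if r.sugar in ("Glc", "Man"))
        return GlycanComposition(hexnac=hexnac, hex=hexose)

    # -- edits (used by the enzyme engine) ---------------------------------

    def without(self, rids: set[int] | list[int], step: str) -> "GlycanTree":
        """Copy of the tree with the given *leaf* residues removed."""
        rids = set(rids)
        for rid in rids:
            kids = set(self._children[rid])
            if kids - rids:
                raise GlycanError(f"residue {rid} still has children outside the removal set")
            if rid == self.root:
                raise GlycanError("cannot remove the reducing-end GlcNAc")
        kept = {rid: r for rid, r in self._residues.items() if rid not in rids}
        return GlycanTree(kept, self.provenance + (step,))

    def with_residue(self, sugar: str, linkage: str, branch: str, parent: int,
                     step: str) -> "GlycanTree":
        new_id = max(self._residues) + 1
        res = dict(self._residues)
        res[new_id] = GlycanResidue(new_id, sugar, linkage, branch, parent)
        return GlycanTree(res, self.provenance + (step,))

    # -- identity ----------------------------------------------------------

    def canonical(self) -> str:
        return format_structure(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GlycanTree):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self) -> int:
        return hash(self.canonical())

    def __repr__(self) -> str:
        return f"GlycanTree({self.composition().label}, {self.canonical()!r})"


# ---------------------------------------------------------------------------
# structure strings (condensed linear dialect, reducing end rightmost)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"(Glc(?!NAc)|GlcNAc|Man)(\((.*?)\))?|\[|\]|(.)")


def format_structure(tree: GlycanTree) -> str:
    """Deterministic condensed string; children ordered a1-2 < a1-3 < a1-6 < b1-4.

    At a branch point the highest-sorted child continues the inline chain and
    the remaining children appear bracketed in ascending linkage order, e.g.
    ``Man(a1-2)Man(a1-6)[Man(a1-2)Man(a1-3)]Man(a1-6)...`` for the B/C arm.
    """

    def fmt(rid: int) -> str:
        r = tree.residue(rid)
        token = r.sugar if r.linkage is None else f"{r.sugar}({r.linkage})"
        kids = sorted(tree.children(rid), key=lambda c: LINKAGES.index(c.linkage))
        if not kids:
            return token
        inline, bracketed = kids[-1], kids[:-1]
        brackets = "".join(f"[{fmt(c.residue_id)}]" for c in bracketed)
        return fmt(inline.residue_id) + brackets + token

    return fmt(tree.root)


def parse_structure(text: str) -> GlycanTree:
    """Parse the condensed dialect back into a tree.

    Branch labels are reassigned from the canonical positions (core chain,
    α1,3 arm = A, α1,6 arm branch point with α1,3 = B and α1,6 = C, Glc = cap);
    ``parse_structure(format_structure(t)) == t`` for every registry structure.
    """
    if not text or not text.strip():
        raise GlycanError("empty structure string")
    tokens: list[tuple[str, str | None]] = []
    pos = 0
    for m in _TOKEN.finditer(text.strip()):
        if m.group(4):
            raise GlycanError(f"unexpected character {m.group(4)!r} at offset {m.start()}")
        if m.group(1):
            link = m.group(3)
            if link is not None and link not in LINKAGES:
                raise GlycanError(f"invalid linkage token {link!r}")
            tokens.append((m.group(1), link))
        else:
            tokens.append((m.group(0), None))
        pos = m.end()
    if not tokens:
        raise GlycanError(f"no residues in {text!r}")

    residues: dict[int, GlycanResidue] = {}
    next_id = [0]

    def new_residue(sugar: str, linkage: str | None, parent: int | None) -> int:
        rid = next_id[0]
        next_id[0] += 1
        residues[rid] = GlycanResidue(rid, sugar, linkage, "core", parent)
        return rid

    # rightmost token is the root; walk right-to-left, brackets open side chains
    sugar, link = tokens[-1]
    if sugar in ("[", "]"):
        raise GlycanError("structure must end with the reducing-end residue")
    if link is not None:
        raise GlycanError("reducing-end residue must not carry a linkage")
    cur = new_residue(sugar, None, None)
    stack: list[int] = []
    for sugar, link in reversed(tokens[:-1]):
        if sugar == "]":
            stack.append(cur)
        elif sugar == "[":
            if not stack:
                raise GlycanError("unbalanced ']' ... '[' in structure string")
            cur = stack.pop()
        else:
            if link is None:
                raise GlycanError(f"non-reducing residue {sugar} lacks a linkage")
            cur = new_residue(sugar, link, cur)
    if stack:
        raise GlycanError("unbalanced brackets in structure string")

    tree = GlycanTree(residues)
    return _relabel_branches(tree)


def _relabel_branches(tree: GlycanTree) -> GlycanTree:
    """Assign canonical branch labels by position (never recomputed afterwards)."""
    labels: dict[int, str] = {}

    def mark(rid: int, label: str) -> None:
        r = tree.residue(rid)
        labels[rid] = "cap" if r.sugar == "Glc" else label
        for c in tree.children(rid):
            mark(c.residue_id, label)

    # core chain: root GlcNAc, its b1-4 GlcNAc, the b1-4 Man
    for r in tree:
        labels.setdefault(r.residue_id, "core")
    beta_man = [r for r in tree if r.sugar == "Man" and r.linkage == "b1-4"]
    if len(beta_man) == 1:
        bm = beta_man[0]
        for arm in tree.children(bm.residue_id):
            if arm.linkage == "a1-3":
                mark(arm.residue_id, "A")
            elif arm.linkage == "a1-6":
                # branch point stays core; its a1-3 subtree is B, a1-6 is C
                labels[arm.residue_id] = "core"
                for sub in tree.children(arm.residue_id):
                    if sub.linkage == "a1-3":
                        mark(sub.residue_id, "B")
                    elif sub.linkage == "a1-6":
                        mark(sub.residue_id, "C")
    relabelled = {
        rid: replace(tree.residue(rid), branch=labels[rid]) for rid in labels
    }
    return GlycanTree(relabelled, tree.provenance)


# ---------------------------------------------------------------------------
# canonical registry
# ---------------------------------------------------------------------------


def _glc3man9() -> GlycanTree:
    """Hardcoded topology of the unprocessed Glc3Man9GlcNAc2 precursor."""
    R = GlycanResidue
    res = [
        R(0, "GlcNAc", None, "core", None),       # reducing end
        R(1, "GlcNAc", "b1-4", "core", 0),
        R(2, "Man", "b1-4", "core", 1),           # core beta-mannose
        R(3, "Man", "a1-3", "A", 2),              # A-branch stem
        R(4, "Man", "a1-2", "A", 3),
        R(5, "Man", "a1-2", "A", 4),              # A-tip (UGGT/Glc acceptor)
        R(6, "Glc", "a1-3", "cap", 5),
        R(7, "Glc", "a1-3", "cap", 6),
        R(8, "Glc", "a1-2", "cap", 7),            # outermost, GCSI substrate
        R(9, "Man", "a1-6", "core", 2),           # B/C branch point
        R(10, "Man", "a1-3", "B", 9),             # B-branch stem
        R(11, "Man", "a1-2", "B", 10),            # B-tip
        R(12, "Man", "a1-6", "C", 9),             # C-branch stem (OS9 signal site)
        R(13, "Man", "a1-2", "C", 12),            # C-tip (MNS4/MNS5 substrate)
    ]
    return GlycanTree({r.residue_id: r for r in res}, ("canonical:Glc3Man9GlcNAc2",))


_REGISTRY_CACHE: dict[str, GlycanTree] | None = None


def _registry() -> dict[str, GlycanTree]:
    """Name → tree; every entry except the root derived by enzyme rules."""
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        from . import enzymes  # deferred: enzymes imports this module

        root = _glc3man9()
        glc2 = enzymes.apply_gcs1(root).product
        glc1man9 = enzymes.apply_gcs2(glc2).product
        man9 = enzymes.apply_gcs2(glc1man9).product
        _REGISTRY_CACHE = {
            "Glc3Man9GlcNAc2": root,
            "Glc2Man9GlcNAc2": glc2,
            "Glc1Man9GlcNAc2": glc1man9,
            "Man9GlcNAc2": man9,
            "Glc1Man8GlcNAc2": enzymes.apply_mns45(glc1man9).product,
            "Glc1Man7GlcNAc2": enzymes.apply_mns45(glc1man9, extended=True).product,
            # Man8 isomers named by the branch whose tip was removed
            "Man8GlcNAc2-A": enzymes.apply_endoM(glc1man9).product,
            "Man8GlcNAc2-B": enzymes.MNS45_B.apply(man9).product,
            "Man8GlcNAc2-C": enzymes.MNS45_C.apply(man9).product,
        }
    return _REGISTRY_CACHE


def registry_names() -> list[str]:
    return list(_registry())


def build_canonical(name: str) -> GlycanTree:
    """Return the registry structure for ``name``.

    The Glc3Man9GlcNAc2 topology is hardcoded; every other entry is derived
    from it by enzyme-engine rule applications, so registry structures carry
    their derivation in ``provenance``.
    """
    try:
        return _registry()[name]
    except KeyError:
        raise GlycanError(
            f"unknown canonical structure {name!r}; known: {', '.join(_registry())}"
        ) from None


def structure_name(tree: GlycanTree) -> str | None:
    """Registry name of ``tree`` if it is a canonical structure, else None."""
    canon = tree.canonical()
    for name, t in _registry().items():
        if t.canonical() == canon:
            return name
    return None


def composition_of(tree: GlycanTree) -> GlycanComposition:
    """MS-visible composition of a tree (module-level alias)."""
    return tree.composition()


def composition_mass(comp: GlycanComposition, released: bool = False) -> float:
    """Neutral monoisotopic mass of a composition (module-level alias)."""
    return comp.mass(released=released)
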
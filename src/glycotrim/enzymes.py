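"""Deterministic rewrite rules for ER N-glycan processing enzymes.

Each enzyme is a rule over a :class:`~glycotrim.glycan.GlycanTree`:

* GCSI removes the single outermost α1,2-linked glucose of the triglucose cap.
* GCSII removes one terminal α1,3-linked glucose per application.
* UGGT re-adds one α1,3-glucose to the A-branch tip of a glucose-free glycan
  whose A-branch is intact (the reglucosylation step of the CNX/CRT cycle).
* MNS4/MNS5 remove the C-branch terminal α1,2-mannose, exposing the α1,6
  mannose recognised by OS9 as the degradation signal; an extended mode also
  trims the B-tip, giving the fully processed Glc1Man7GlcNAc2.
* Jack bean α-mannosidase (JBM), the diagnostic exoglycosidase, iteratively
  removes every terminal α-linked mannose; glucose is never a substrate, so a
  glucose-capped A-branch is fully protected and the β1,4 core mannose always
  survives.  The limit digest therefore separates isobaric structures:
  Man8GlcNAc2 trims to Hex1HexNAc2 while Glc1Man7GlcNAc2 stops at Hex5HexNAc2.
* EndoM (endo-α-mannosidase) removes the Glcα1,3-Man disaccharide from the
  A-branch of a monoglucosylated glycan, destroying the UGGT acceptor.

Rules conserve residues: composition(product) + Σ released = composition(input).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .glycan import (
    GlycanComposition,
    GlycanResidue,
    GlycanTree,
    build_canonical,
    structure_name,
)

HEX1 = GlycanComposition(hex=1)
HEX2 = GlycanComposition(hex=2)


class NotASubstrate(ValueError):
    """The tree does not satisfy the enzyme's structural requirement."""


@dataclass(frozen=True)
class DigestionResult:
    product: GlycanTree
    released: tuple[GlycanComposition, ...]
    steps: tuple[str, ...]

    @property
    def released_composition(self) -> GlycanComposition:
        out = GlycanComposition()
        for c in self.released:
            out = out + c
        return out


def _residue_sort_key(tree: GlycanTree, r: GlycanResidue):
    # deterministic choice among equivalent sites: deepest first, then by
    # canonical branch order so repeated runs enumerate identically
    return (-tree.depth(r.residue_id), ("core", "A", "B", "C", "cap").index(r.branch),
            r.residue_id)


@dataclass(frozen=True)
class EnzymeRule:
    """A single-site rewrite; ``applications`` enumerates every legal site."""

    name: str
    sugar: str
    linkage: str
    branch: str | None = None  # restrict to one branch (MNS4/5 sub-rules)

    def sites(self, tree: GlycanTree) -> list[GlycanResidue]:
        hits = tree.find(sugar=self.sugar, linkage=self.linkage,
                         branch=self.branch, terminal=True)
        return sorted(hits, key=lambda r: _residue_sort_key(tree, r))

    def applications(self, tree: GlycanTree) -> list[DigestionResult]:
        out = []
        for site in self.sites(tree):
            step = f"{self.name}:-{site.sugar}@{site.branch}"
            product = tree.without({site.residue_id}, step)
            out.append(DigestionResult(product, (HEX1,), (step,)))
        return out

    def apply(self, tree: GlycanTree) -> DigestionResult:
        apps = self.applications(tree)
        if not apps:
            raise NotASubstrate(f"{self.name}: no terminal {self.sugar} ({self.linkage})")
        return apps[0]


GCSI = EnzymeRule("GCSI", "Glc", "a1-2")
GCSII = EnzymeRule("GCSII", "Glc", "a1-3")
MNS45_C = EnzymeRule("MNS45-C", "Man", "a1-2", branch="C")
MNS45_B = EnzymeRule("MNS45-B", "Man", "a1-2", branch="B")
#: non-specific ER/Golgi-type α1,2-mannosidase used for isomer enumeration
A12_MANNOSIDASE = EnzymeRule("generic-a12-mannosidase", "Man", "a1-2")


@dataclass(frozen=True)
class UggtRule:
    """Reglucosylation: +1 α1,3-Glc on the A-tip of a glucose-free glycan."""

    name: str = "UGGT"

    def applications(self, tree: GlycanTree) -> list[DigestionResult]:
        if tree.find(sugar="Glc"):
            return []
        tip = tree.a_tip()
        if tip is None or not tree.is_terminal(tip.residue_id):
            return []
        step = "UGGT:+Glc@A-tip"
        product = tree.with_residue("Glc", "a1-3", "cap", tip.residue_id, step)
        return [DigestionResult(product, (), (step,))]

    def apply(self, tree: GlycanTree) -> DigestionResult:
        apps = self.applications(tree)
        if not apps:
            raise NotASubstrate(
                "UGGT: glycan already glucosylated or A-branch tip missing")
        return apps[0]


UGGT = UggtRule()


@dataclass(frozen=True)
class EndoMRule:
    """Removes the Glcα1,3-Man disaccharide from the A-branch tip."""

    name: str = "EndoM"

    def applications(self, tree: GlycanTree) -> list[DigestionResult]:
        glcs = tree.find(sugar="Glc")
        if len(glcs) != 1:
            return []  # action on di/tri-glucosylated glycans is disputed; rejected
        glc = glcs[0]
        if glc.linkage != "a1-3" or not tree.is_terminal(glc.residue_id):
            return []
        tip = tree.a_tip()
        if tip is None or glc.parent != tip.residue_id:
            return []
        step = "EndoM:-GlcMan@A-tip"
        product = tree.without({glc.residue_id, tip.residue_id}, step)
        return [DigestionResult(product, (HEX2,), (step,))]

    def apply(self, tree: GlycanTree) -> DigestionResult:
        apps = self.applications(tree)
        if not apps:
            raise NotASubstrate(
                "EndoM: requires exactly one Glc, α1,3-linked to the A-branch tip")
        return apps[0]


ENDOM = EndoMRule()

RULES = {
    "GCSI": GCSI,
    "GCSII": GCSII,
    "UGGT": UGGT,
    "MNS45-C": MNS45_C,
    "MNS45-B": MNS45_B,
    "EndoM": ENDOM,
    "generic-a12-mannosidase": A12_MANNOSIDASE,
}


# ---------------------------------------------------------------------------
# enzyme front-ends
# ---------------------------------------------------------------------------


def apply_gcs1(tree: GlycanTree) -> DigestionResult:
    """Remove the outermost α1,2-Glc of the triglucose cap."""
    return GCSI.apply(tree)


def apply_gcs2(tree: GlycanTree) -> DigestionResult:
    """Remove one terminal α1,3-Glc."""
    return GCSII.apply(tree)


def apply_uggt(tree: GlycanTree) -> DigestionResult:
    """Add one α1,3-Glc to the A-branch tip (reglucosylation)."""
    return UGGT.apply(tree)


def apply_endoM(tree: GlycanTree) -> DigestionResult:
    """Remove the Glcα1,3-Man disaccharide from a monoglucosylated glycan."""
    return ENDOM.apply(tree)


def apply_mns45(tree: GlycanTree, extended: bool = False) -> DigestionResult:
    """Trim the C-tip α1,2-Man (exposing the OS9 signal); with ``extended``
    also trim the B-tip, yielding the fully processed Glc1Man7-type product.
    """
    first = MNS45_C.apply(tree)
    if not extended:
        return first
    second = MNS45_B.apply(first.product)
    return DigestionResult(second.product, first.released + second.released,
                           first.steps + second.steps)


def jbm_digest(tree: GlycanTree, iterations: int | None = None) -> DigestionResult:
    """Jack bean α-mannosidase digestion.

    Each iteration removes *all* currently terminal α-linked mannoses
    simultaneously; ``iterations=None`` runs to the fixpoint (limit digest).
    A tree with no substrate is returned unchanged (identity, not an error),
    so the limit digest is idempotent.
    """
    if iterations is not None and iterations < 0:
        raise ValueError("iterations must be >= 0")
    product = tree
    released: tuple[GlycanComposition, ...] = ()
    steps: tuple[str, ...] = ()
    rounds = 0
    while iterations is None or rounds < iterations:
        victims = {
            r.residue_id
            for r in product.terminal_residues()
            if r.sugar == "Man" and r.linkage is not None and r.linkage.startswith("a")
        }
        if not victims:
            break
        step = f"JBM:round{rounds + 1}:-{len(victims)}Man"
        product = product.without(victims, step)
        released = released + (HEX1,) * len(victims)
        steps = steps + (step,)
        rounds += 1
    return DigestionResult(product, released, steps)


# ---------------------------------------------------------------------------
# reachable-structure enumeration and isobaric-structure inference
# ---------------------------------------------------------------------------


def reachable_structures(
    start: GlycanTree,
    rules: list[str | EnzymeRule | UggtRule | EndoMRule],
    max_steps: int | None = None,
) -> set[GlycanTree]:
    """Breadth-first closure of single rule applications, start included.

    States are deduplicated by tree isomorphism (canonical structure string);
    residue counts are bounded, so the closure is finite and terminates.
    """
    if max_steps is not None and max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    rule_objs = [RULES[r] if isinstance(r, str) else r for r in rules]
    seen: dict[str, GlycanTree] = {start.canonical(): start}
    frontier = deque([(start, 0)])
    while frontier:
        tree, depth = frontier.popleft()
        if max_steps is not None and depth >= max_steps:
            continue
        for rule in rule_objs:
            for res in rule.applications(tree):
                key = res.product.canonical()
                if key not in seen:
                    seen[key] = res.product
                    frontier.append((res.product, depth + 1))
    return set(seen.values())


#: rule set from which observable ER glycoforms are enumerated
ER_RULESET = ["GCSI", "GCSII", "UGGT", "generic-a12-mannosidase", "MNS45-C", "MNS45-B"]


@dataclass(frozen=True)
class IsomerCandidate:
    structure: GlycanTree
    name: str
    glc_count: int
    jbm_limit: GlycanComposition
    endoM_sensitive: bool
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class InferenceResult:
    candidates: tuple[IsomerCandidate, ...]
    diagnostic: str = ""

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)


def _candidate_name(tree: GlycanTree) -> str:
    named = structure_name(tree)
    if named is not None:
        return named
    glc = len(tree.find(sugar="Glc"))
    man = len(tree.find(sugar="Man"))
    return f"Glc{glc}Man{man}GlcNAc2/{tree.canonical()}"


def infer_isomer(
    observed: GlycanComposition,
    jbm_limit: GlycanComposition | None = None,
    endoM_sensitive: bool | None = None,
    elutes_off_standard: bool | None = None,
    max_glc: int = 1,
) -> InferenceResult:
    """Rank candidate structures for an observed isobaric composition.

    Candidates are the ER-reachable structures (from Glc3Man9GlcNAc2 under
    glucosidases, UGGT, α1,2-mannosidase and MNS4/5 sub-rules) matching the
    observed Hex/HexNAc counts, filtered by diagnostic digestion evidence:
    the predicted JBM limit-digest composition and EndoM susceptibility.
    Chromatographic separation from glucose-free standards only reorders
    (glucosylated candidates first when ``elutes_off_standard``); the default
    order is glucose count descending, then name, which coincides with it.
    Glucosylation states are restricted to ``max_glc`` (default 1: GCSI/GCSII
    act co-translationally; raise it to consider Glc2/Glc3 species).
    """
    if observed.hexnac != 2:
        raise ValueError("inference is defined for HexNAc2 oligomannosidic glycans")
    pool = reachable_structures(build_canonical("Glc3Man9GlcNAc2"), ER_RULESET)
    rejected: list[str] = []
    out: list[IsomerCandidate] = []
    for tree in pool:
        if tree.composition() != observed:
            continue
        glc = len(tree.find(sugar="Glc"))
        name = _candidate_name(tree)
        if glc > max_glc:
            rejected.append(f"{name}: Glc{glc} exceeds max_glc={max_glc}")
            continue
        limit = jbm_digest(tree).product.composition()
        sensitive = bool(ENDOM.applications(tree))
        if jbm_limit is not None and limit != jbm_limit:
            rejected.append(f"{name}: JBM limit {limit.label} != {jbm_limit.label}")
            continue
        if endoM_sensitive is not None and sensitive != endoM_sensitive:
            rejected.append(f"{name}: EndoM-sensitive={sensitive}")
            continue
        evidence = [f"JBM limit {limit.label}",
                    "EndoM-sensitive" if sensitive else "EndoM-resistant"]
        if elutes_off_standard and glc > 0:
            evidence.append("glucosylated; consistent with elution off Man-standards")
        out.append(IsomerCandidate(tree, name, glc, limit, sensitive, tuple(evidence)))
    out.sort(key=lambda c: (-c.glc_count, c.name))
    diagnostic = ""
    if not out:
        diagnostic = (
            f"no ER-reachable structure matches {observed.label} under the given "
            f"evidence; rejected: {'; '.join(rejected) or 'none matched composition'}"
        )
    return InferenceResult(tuple(out), diagnostic)
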
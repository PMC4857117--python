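"""mtDNA variants in position-based mutation notation, and haplotype profiles.

Variants are reported relative to a reference sequence (rCRS or RSRS) in the
standard forensic/phylogeographic shorthand: a bare position ("16126") is a
transition; a base suffix ("16265A") a transversion to that base; "d" a
deletion ("522d"); a dot-index an insertion ("573.1C" = one C inserted after
np 573); "@" marks a reversion toward the ancestral state ("@152"); R/Y
suffixes mark point heteroplasmies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

MT_LENGTH = 16569

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_HETEROPLASMY = {"R", "Y"}

_TOKEN_RE = re.compile(
    r"""^(?P<rev>@)?
        (?P<pos>\d{1,5})
        (?:
            (?P<del>d(?:el)?) |
            \.(?P<idx>\d+)(?P<ins>[ACGT]+) |
            (?P<base>[ACGTRY])
        )?$""",
    re.VERBOSE | re.IGNORECASE,
)


class VariantError(ValueError):
    """Raised for malformed variant tokens or inconsistent variant data."""


@dataclass(frozen=True, order=True)
class Variant:
    """One mutation event at a nucleotide position of the mitogenome.

    ``kind`` is one of ``transition``, ``transversion``, ``insertion``,
    ``deletion``. For insertions, ``insert_index`` is the dot-index and
    ``insert_seq`` the inserted bases. ``derived_base`` is set for
    transversions and heteroplasmic calls; pure transitions and deletions
    leave it empty. ``is_reversion`` carries the "@" mark and
    ``is_heteroplasmy`` flags R/Y calls.
    """

    position: int
    kind: str = "transition"
    derived_base: str = ""
    insert_index: int = 0
    insert_seq: str = ""
    is_reversion: bool = False
    is_heteroplasmy: bool = False

    def __post_init__(self):
        if not (1 <= self.position <= MT_LENGTH):
            raise VariantError(f"position {self.position} outside 1..{MT_LENGTH}")
        if self.kind not in {"transition", "transversion", "insertion", "deletion"}:
            raise VariantError(f"unknown variant kind {self.kind!r}")
        if (self.kind == "insertion") != (self.insert_index > 0):
            raise VariantError("insertion requires a positive insert_index (and only insertions may have one)")
        if self.kind == "insertion" and not self.insert_seq:
            raise VariantError("insertion requires insert_seq")
        if self.is_heteroplasmy and self.derived_base not in _HETEROPLASMY:
            raise VariantError("heteroplasmy flag requires derived_base R or Y")

    @property
    def site(self) -> tuple[int, int]:
        """Identity of the mutated site: (position, insert_index)."""
        return (self.position, self.insert_index)

    def __str__(self) -> str:
        return render_variant(self)


def parse_variant(token: str) -> Variant:
    """Parse one notation token into a :class:`Variant`.

    A purely numeric token is a transition; see module docstring for the
    suffix grammar. Raises :class:`VariantError` on malformed tokens,
    naming the offending token.
    """
    if not token or not token.strip():
        raise VariantError("empty variant token")
    tok = token.strip()
    m = _TOKEN_RE.match(tok)
    if m is None:
        raise VariantError(f"malformed variant token {token!r}")
    pos = int(m.group("pos"))
    if not (1 <= pos <= MT_LENGTH):
        raise VariantError(f"position out of range in token {token!r}")
    rev = m.group("rev") is not None
    if m.group("del"):
        return Variant(pos, "deletion", is_reversion=rev)
    if m.group("idx"):
        idx = int(m.group("idx"))
        if idx < 1:
            raise VariantError(f"insertion index must be >=1 in token {token!r}")
        return Variant(pos, "insertion", insert_index=idx,
                       insert_seq=m.group("ins").upper(), is_reversion=rev)
    base = m.group("base")
    if base is None:
        return Variant(pos, "transition", is_reversion=rev)
    base = base.upper()
    if base in _HETEROPLASMY:
        # heteroplasmic transition call (mixture of ancestral and derived)
        return Variant(pos, "transition", derived_base=base,
                       is_reversion=rev, is_heteroplasmy=True)
    return Variant(pos, "transversion", derived_base=base, is_reversion=rev)


def render_variant(v: Variant) -> str:
    """Canonical string form of a variant; round-trips through the parser."""
    prefix = "@" if v.is_reversion else ""
    if v.kind == "deletion":
        return f"{prefix}{v.position}d"
    if v.kind == "insertion":
        return f"{prefix}{v.position}.{v.insert_index}{v.insert_seq}"
    if v.derived_base:
        return f"{prefix}{v.position}{v.derived_base}"
    return f"{prefix}{v.position}"


def parse_profile(text: str) -> frozenset[Variant]:
    """Parse a whitespace-separated list of variant tokens."""
    variants = [parse_variant(t) for t in text.split()]
    sites = [v.site for v in variants]
    if len(set(sites)) != len(sites):
        dup = sorted({s for s in sites if sites.count(s) > 1})
        raise VariantError(f"duplicate variants at site(s) {dup}")
    return frozenset(variants)


def render_profile(variants) -> str:
    """Canonical space-separated rendering, sorted by (position, index)."""
    return " ".join(render_variant(v)
                    for v in sorted(variants, key=lambda v: (v.site, str(v))))


# ---------------------------------------------------------------------------
# Haplotypes

WHOLE_RANGE = ((1, MT_LENGTH),)
# hypervariable segment I plus the rest of the control region, in rCRS coords
CONTROL_REGION_RANGE = ((16024, MT_LENGTH), (1, 576))
HVS1_RANGE = ((16024, 16383),)

DEFAULT_REGIONS = (
    "Arabian Peninsula", "Fertile Crescent", "Iran", "Eastern Africa",
    "Europe", "South Asia", "North Africa", "Caucasus", "unassigned",
)


@dataclass(frozen=True)
class Haplotype:
    """A sampled mitogenome: identifier, origin labels and variant profile.

    ``range`` is a tuple of inclusive (start, end) np intervals actually
    sequenced (whole molecule by default); variants must fall inside it.
    """

    sample_id: str
    population: str = ""
    region: str = "unassigned"
    variants: frozenset[Variant] = frozenset()
    reference: str = "rCRS"
    range: tuple[tuple[int, int], ...] = WHOLE_RANGE

    def __post_init__(self):
        sites = [v.site for v in self.variants]
        if len(set(sites)) != len(sites):
            raise VariantError(f"{self.sample_id}: duplicate variants at one site")
        outside = [v for v in self.variants if not self.covers(v.position)]
        if outside:
            raise VariantError(
                f"{self.sample_id}: variants outside declared range: "
                + render_profile(outside))

    def covers(self, position: int) -> bool:
        return any(lo <= position <= hi for lo, hi in self.range)


# ---------------------------------------------------------------------------
# Variant calling against a reference-aligned sequence

_IUPAC = set("ACGTRYSWKMBDHVN-")


def call_variants(sequence: str, reference: str) -> frozenset[Variant]:
    """Call variants from a reference-aligned sequence.

    ``sequence`` must be in reference coordinates and of equal length;
    "-" denotes a deletion. Differences are classified as transition,
    transversion or deletion by the base change; heteroplasmic R/Y calls
    compatible with a transition are flagged as such.
    """
    ref = reference.upper().replace("\n", "")
    seq = sequence.upper().replace("\n", "")
    if len(seq) != len(ref):
        raise VariantError(
            f"sequence length {len(seq)} does not match reference length {len(ref)}")
    bad = sorted(set(seq) - _IUPAC)
    if bad:
        raise VariantError(f"non-IUPAC characters in sequence: {bad}")
    out = []
    for i, (r, s) in enumerate(zip(ref, seq), start=1):
        if s == r or s == "N":
            continue
        if s == "-":
            out.append(Variant(i, "deletion"))
        elif s in _HETEROPLASMY:
            out.append(Variant(i, "transition", derived_base=s, is_heteroplasmy=True))
        elif s in TRANSITION_PARTNER and s == TRANSITION_PARTNER.get(r, ""):
            out.append(Variant(i, "transition"))
        elif s in "ACGT":
            out.append(Variant(i, "transversion", derived_base=s))
        else:
            # other ambiguity codes: record as heteroplasmic-style call
            out.append(Variant(i, "transition", derived_base="R" if r in PURINES else "Y",
                               is_heteroplasmy=True))
    return frozenset(out)


def mutate_sequence(reference: str, variants) -> str:
    """Apply substitution/deletion variants to a reference (test oracle for
    :func:`call_variants`). Insertions are not representable in reference
    coordinates and are rejected."""
    seq = list(reference.upper())
    for v in variants:
        if v.kind == "insertion":
            raise VariantError("cannot place insertions in reference coordinates")
        r = seq[v.position - 1]
        if v.kind == "deletion":
            seq[v.position - 1] = "-"
        elif v.derived_base:
            seq[v.position - 1] = v.derived_base
        else:
            seq[v.position - 1] = TRANSITION_PARTNER[r]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Exclusion policies

@dataclass(frozen=True)
class ExclusionPolicy:
    """Sites conventionally excluded from mtDNA phylogenies and dating.

    ``excluded_positions`` (np 16519) and the length-variant zones (the
    C-stretches around np 309/315 and the AC indel zone np 515-522) apply to
    phylogeny construction; clade identification additionally drops the
    unreliable np 60; dating drops 16519 plus the hypervariable 16182C /
    16183C transversions.
    """

    excluded_positions: frozenset[int] = frozenset({16519})
    c_stretch_zones: tuple[tuple[int, int], ...] = ((302, 316),)
    ac_indel_zone: tuple[int, int] = (513, 524)
    excluded_for_clade_id: frozenset[int] = frozenset({60})
    excluded_hypervariable: frozenset[str] = frozenset({"16182C", "16183C"})
    count_heteroplasmies: bool = True

    def _in_zone(self, v: Variant) -> bool:
        if v.kind in ("insertion", "deletion"):
            for lo, hi in self.c_stretch_zones:
                if lo <= v.position <= hi:
                    return True
            lo, hi = self.ac_indel_zone
            if lo <= v.position <= hi:
                return True
        return False

    def excludes(self, v: Variant, context: str) -> bool:
        if context == "phylogeny":
            return v.position in self.excluded_positions or self._in_zone(v)
        if context == "clade_id":
            return (v.position in self.excluded_positions
                    or v.position in self.excluded_for_clade_id
                    or self._in_zone(v))
        if context == "ml_dating":
            bare = f"{v.position}{v.derived_base}"
            return (v.position in self.excluded_positions
                    or bare in self.excluded_hypervariable)
        raise ValueError(f"unknown exclusion context {context!r}")


DEFAULT_POLICY = ExclusionPolicy()


def apply_exclusions(variants, policy: ExclusionPolicy | None = None,
                     context: str = "phylogeny") -> frozenset[Variant]:
    """Filter a variant set under the named exclusion context.

    Contexts: ``phylogeny`` (np 16519 + C-stretch and AC-indel length
    variants), ``clade_id`` (additionally np 60), ``ml_dating`` (np 16519
    plus 16182C/16183C). Idempotent; input is not modified.
    """
    policy = policy or DEFAULT_POLICY
    if context not in ("phylogeny", "clade_id", "ml_dating"):
        raise ValueError(f"unknown exclusion context {context!r}")
    kept = frozenset(v for v in variants if not policy.excludes(v, context))
    if not policy.count_heteroplasmies:
        kept = frozenset(v for v in kept if not v.is_heteroplasmy)
    return kept


# ---------------------------------------------------------------------------
# Reference conversion (rCRS <-> RSRS rebasing)

def convert_reference(haplotype: Haplotype, target: str,
                      diff_table) -> Haplotype:
    """Re-express a haplotype's profile relative to the other reference.

    ``diff_table`` is the variant set separating the two references (the
    profile of the target reference relative to the current one, or vice
    versa: the operation is symmetric). The output profile is the symmetric
    difference of the input profile and the diff table restricted to the
    haplotype's sequenced range; converting twice restores the original.
    """
    if target == haplotype.reference:
        return haplotype
    relevant = {v for v in diff_table if haplotype.covers(v.position)}
    uncovered = [v for v in diff_table if not haplotype.covers(v.position)]
    # positions of the diff outside the sequenced range cannot be rebased;
    # only an error if the haplotype claims whole-molecule coverage
    if uncovered and haplotype.range == WHOLE_RANGE:
        raise VariantError(
            "diff table positions outside haplotype range: "
            + render_profile(uncovered))
    by_site_profile = {v.site: v for v in haplotype.variants}
    out = set(haplotype.variants)
    for d in relevant:
        if d.site in by_site_profile:
            out.discard(by_site_profile[d.site])
        else:
            out.add(d)
    return replace(haplotype, reference=target, variants=frozenset(out))
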
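"""Protein constructs, point substitutions and k-mer windows.

A *construct* is one test protein (e.g. a wild-type coagulation factor or an
engineered variant of it). Coordinates are 1-based inclusive throughout the
package. Each construct carries a ``numbering_offset`` mapping local position
1 onto whatever reference numbering the substitutions are expressed in
(mature-protein numbering, typically), so that variant definitions such as
"E296V" can be applied without hard-coding a signal-peptide convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import OutOfBoundsError, ReferenceMismatchError

#: The 20 canonical amino acids. Ambiguity codes (B, J, Z, X) and the
#: non-standard letters O/U are rejected: eluted-ligand identifications are
#: reported over the canonical alphabet.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinConstruct:
    """One test protein.

    Parameters
    ----------
    id:
        Short label, e.g. ``"WT"``, ``"VA"``, ``"DI-1"``.
    sequence:
        Amino-acid sequence (uppercased on construction).
    numbering_offset:
        Reference position of local residue 1, minus 1. Local position ``p``
        corresponds to reference position ``p + numbering_offset``.
    """

    id: str
    sequence: str
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"construct {self.id!r}: empty sequence")
        bad = set(seq) - CANONICAL_AA
        if bad:
            raise ValueError(
                f"construct {self.id!r}: non-canonical letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def local_position(self, reference_position: int) -> int:
        """Convert a reference-numbering position to a local 1-based index."""
        return reference_position - self.numbering_offset

    def residue_at(self, local_position: int) -> str:
        if not 1 <= local_position <= len(self.sequence):
            raise OutOfBoundsError(
                f"construct {self.id!r}: local position {local_position} outside "
                f"[1, {len(self.sequence)}]"
            )
        return self.sequence[local_position - 1]


@dataclass(frozen=True)
class Substitution:
    """A single amino-acid substitution in reference numbering."""

    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        for name in ("ref_aa", "alt_aa"):
            aa = getattr(self, name).upper()
            object.__setattr__(self, name, aa)
            if aa not in CANONICAL_AA:
                raise ValueError(f"{name} {aa!r} is not a canonical amino acid")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"substitution at {self.position}: ref and alt are both {self.ref_aa!r}"
            )

    @property
    def inverse(self) -> "Substitution":
        return Substitution(self.position, self.alt_aa, self.ref_aa)

    def __str__(self) -> str:  # e.g. "E296V"
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class RegionWindow:
    """A 1-based inclusive interval in local construct coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid window [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


def apply_substitutions(
    base: ProteinConstruct,
    subs: list[Substitution],
    new_id: str | None = None,
) -> ProteinConstruct:
    """Apply point substitutions to a construct.

    Every substitution's ``ref_aa`` must match the base sequence at
    ``position - numbering_offset``; a mismatch raises
    :class:`ReferenceMismatchError` naming the offending position so that a
    wrong ``numbering_offset`` is caught immediately rather than silently
    producing the wrong variant.
    """
    seq = list(base.sequence)
    for sub in subs:
        local = base.local_position(sub.position)
        if not 1 <= local <= len(seq):
            raise OutOfBoundsError(
                f"substitution {sub}: local position {local} outside "
                f"[1, {len(seq)}] (offset {base.numbering_offset})"
            )
        found = seq[local - 1]
        if found != sub.ref_aa:
            raise ReferenceMismatchError(
                f"substitution {sub}: construct {base.id!r} has {found!r} at "
                f"reference position {sub.position} (local {local}), expected "
                f"{sub.ref_aa!r}"
            )
        seq[local - 1] = sub.alt_aa
    return replace(base, sequence="".join(seq), id=new_id or base.id)


def generate_kmers(
    c: ProteinConstruct, k: int = 15
) -> list[tuple[int, str]]:
    """All overlapping k-mers of a construct as ``(start, peptide)`` pairs.

    Starts are 1-based and consecutive (step 1). Returns an empty list when
    the sequence is shorter than ``k``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = c.sequence
    return [(i + 1, seq[i : i + k]) for i in range(len(seq) - k + 1)]


def mutation_window(
    subs: list[Substitution], c: ProteinConstruct, k: int = 15
) -> RegionWindow:
    """Minimal window containing every k-mer that overlaps a substitution.

    The window spans from the first start of a k-mer overlapping any
    substituted position to the end of the last such k-mer, clipped to the
    sequence bounds. This is the "mutation region" used when restricting
    peptide counts or binding heatmaps to the engineered positions.
    """
    if not subs:
        raise ValueError("mutation_window requires at least one substitution")
    length = len(c)
    last_start = length - k + 1
    if last_start < 1:
        raise OutOfBoundsError(f"construct {c.id!r} shorter than k={k}")
    starts: set[int] = set()
    for sub in subs:
        local = c.local_position(sub.position)
        if not 1 <= local <= length:
            raise OutOfBoundsError(f"substitution {sub}: out of bounds")
        lo = max(1, local - k + 1)
        hi = min(local, last_start)
        starts.update(range(lo, hi + 1))
    return RegionWindow(min(starts), min(length, max(starts) + k - 1))
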
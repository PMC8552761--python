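"""Degenerate-primer in-silico PCR and clone-to-copy assignment.

Locates binding sites of an IUPAC-degenerate primer pair on a template (both
orientations), extracts the would-be amplicons, and assigns sequenced clones
of such an amplicon to their most similar reference copy — the computational
counterpart of cloning a shared amplicon from a tandemly duplicated gene
family and attributing each clone to one family member of one haplotype.

Matching is exact outside degenerate positions (a configurable number of
mismatches can be allowed); product length counts both primer footprints, the
standard PCR convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"primer {self.name}: empty sequence")
        seq = self.sequence.upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC_CODES:
                raise ValueError(
                    f"primer {self.name}: invalid IUPAC code {ch!r} at position {i + 1}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AmpliconResult:
    template_id: str
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int
    sequence: str
    fwd_primer: str
    rev_primer: str
    orientation: str  # "+" fwd on plus strand, "-" fwd on minus strand

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CloneAssignment:
    clone_id: str
    best_reference: str
    identity: float
    status: str  # "assigned" | "ambiguous"


def iupac_match(code: str, base: str) -> bool:
    """True iff ``base`` belongs to the expansion of the IUPAC ``code``."""
    code = code.upper()
    base = base.upper()
    if code not in IUPAC_CODES:
        raise ValueError(f"invalid IUPAC code {code!r}")
    if base not in "ACGT":
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    return base in IUPAC_CODES[code]


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving IUPAC degeneracy (e.g. M <-> K)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _primer_regex(primer_seq: str) -> re.Pattern:
    parts = []
    for ch in primer_seq:
        bases = sorted(IUPAC_CODES[ch])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("".join(parts))


def _find_sites(template: str, primer_seq: str) -> list[int]:
    """0-based start positions where the primer matches the plus strand."""
    pattern = _primer_regex(primer_seq)
    # lookahead wrapper reports overlapping matches too
    return [m.start() for m in re.finditer(f"(?=({pattern.pattern}))", template)]


def insilico_pcr(
    template: str,
    fwd: Primer,
    rev: Primer,
    max_product: int = 5000,
    template_id: str = "template",
) -> list[AmpliconResult]:
    """All PCR products of a primer pair on one template, both orientations.

    A product requires the forward primer on one strand and the reverse
    primer's reverse complement downstream on the same strand, within
    ``max_product`` bases.  No site yields an empty list, never an error.
    """
    if max_product <= len(fwd) + len(rev):
        raise ValueError("max_product must exceed the combined primer length")
    template = template.upper()
    products = []
    for orientation, p5, p3 in (("+", fwd, rev), ("-", rev, fwd)):
        starts5 = _find_sites(template, p5.sequence)
        starts3 = _find_sites(template, reverse_complement(p3.sequence))
        for s5 in starts5:
            for s3 in starts3:
                end = s3 + len(p3)  # 0-based exclusive product end
                if end - s5 < len(p5) + len(p3):
                    continue
                if end - s5 > max_product:
                    continue
                products.append(
                    AmpliconResult(
                        template_id=template_id,
                        start=s5 + 1,
                        end=end,
                        sequence=template[s5:end],
                        fwd_primer=p5.name,
                        rev_primer=p3.name,
                        orientation=orientation,
                    )
                )
    products.sort(key=lambda p: (p.start, p.end, p.orientation))
    return products


def verify_product(product: AmpliconResult, fwd: Primer, rev: Primer) -> bool:
    """Re-check base-by-base that a product's ends match both primers."""
    seq = product.sequence
    p5 = fwd if product.orientation == "+" else rev
    p3 = rev if product.orientation == "+" else fwd
    head_ok = all(iupac_match(c, b) for c, b in zip(p5.sequence, seq))
    tail = seq[-len(p3):]
    tail_ok = all(iupac_match(c, b) for c, b in zip(reverse_complement(p3.sequence), tail))
    return head_ok and tail_ok and product.length == len(seq)


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


_NT_ALIGNER = _nt_aligner()


def _nt_identity(a: str, b: str) -> float:
    alignment = _NT_ALIGNER.align(a, b)[0]
    blocks_a, blocks_b = alignment.aligned
    matches = 0
    cols = 0
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        cols += ea - sa
        matches += sum(x == y for x, y in zip(a[sa:ea], b[sb:eb]))
    return matches / cols if cols else 0.0


def assign_clones(
    clones: Mapping[str, str],
    references: Mapping[str, str],
    tie_tolerance: float = 1e-6,
) -> tuple[list[CloneAssignment], dict[str, int]]:
    """Assign each clone to its arg-max-identity reference copy.

    A clone whose top two reference identities agree within ``tie_tolerance``
    is flagged ambiguous (and excluded from the tally).  The tally preserves
    the order of ``references``.
    """
    if not references:
        raise ValueError("at least one reference sequence is required")
    assignments = []
    tally = {rid: 0 for rid in references}
    for cid, cseq in clones.items():
        if not cseq:
            raise ValueError(f"clone {cid!r} has an empty sequence")
        idents = [(rid, _nt_identity(cseq.upper(), rseq.upper())) for rid, rseq in references.items()]
        idents.sort(key=lambda t: -t[1])
        best_id, best = idents[0]
        runner = idents[1][1] if len(idents) > 1 else -1.0
        if best - runner <= tie_tolerance and len(idents) > 1:
            assignments.append(CloneAssignment(cid, best_id, best, "ambiguous"))
        else:
            assignments.append(CloneAssignment(cid, best_id, best, "assigned"))
            tally[best_id] += 1
    return assignments, tally
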
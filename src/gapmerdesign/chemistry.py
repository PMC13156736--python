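"""Gapmer modification patterns and the 5-10-5 MOE -> 3-10-3 cEt conversion.

Notation (no community standard covers MOE/cEt gapmers): an optional
``GalNAc-`` prefix, a ``[MOE]``/``[cEt]`` wing-chemistry header, lowercase
wing residues, uppercase DNA gap residues, and ``*`` between residues for
phosphorothioate linkages (absent for phosphodiester). The notation is
invertible; :func:`parse_annotation` recovers sequence and pattern.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, replace

from .candgen import GapmerCandidate
from .seqio import DataError

WING_CHEMISTRIES = ("MOE", "cEt")


@dataclass(frozen=True)
class GapmerPattern:
    wing5: int
    gap: int
    wing3: int
    wing_chemistry: str = "MOE"
    backbone: str = "PS"
    conjugate: str = "none"

    def __post_init__(self):
        if self.wing_chemistry not in WING_CHEMISTRIES:
            raise DataError(f"unknown wing chemistry {self.wing_chemistry!r}")
        if self.backbone not in ("PS", "PO"):
            raise DataError(f"unknown backbone {self.backbone!r}")
        if self.conjugate not in ("none", "GalNAc"):
            raise DataError(f"unknown conjugate {self.conjugate!r}")

    @property
    def length(self) -> int:
        return self.wing5 + self.gap + self.wing3

    def __str__(self) -> str:
        return f"{self.wing5}-{self.gap}-{self.wing3}"


MOE_5_10_5 = GapmerPattern(5, 10, 5, "MOE", "PS", "none")
CET_3_10_3 = GapmerPattern(3, 10, 3, "cEt", "PS", "none")


def annotate(aso_sequence: str, pattern: GapmerPattern) -> str:
    """Render the modification pattern onto the oligo sequence."""
    if len(aso_sequence) != pattern.length:
        raise DataError(
            f"pattern {pattern} sums to {pattern.length} != sequence length "
            f"{len(aso_sequence)}")
    seq = aso_sequence.upper()
    residues = []
    for i, base in enumerate(seq):
        in_wing = i < pattern.wing5 or i >= pattern.wing5 + pattern.gap
        residues.append(base.lower() if in_wing else base)
    sep = "*" if pattern.backbone == "PS" else ""
    prefix = "GalNAc-" if pattern.conjugate == "GalNAc" else ""
    return f"{prefix}[{pattern.wing_chemistry}]{sep.join(residues)}"


_ANNOT_RE = re.compile(r"^(GalNAc-)?\[(\w+)\]([acgtACGT*]+)$")


def parse_annotation(text: str) -> tuple[str, GapmerPattern]:
    """Invert :func:`annotate`: recover (sequence, pattern)."""
    m = _ANNOT_RE.match(text)
    if not m:
        raise DataError(f"unparseable annotation {text!r}")
    conjugate = "GalNAc" if m.group(1) else "none"
    chemistry = m.group(2)
    body = m.group(3)
    backbone = "PS" if "*" in body else "PO"
    residues = body.replace("*", "")
    wing5 = len(residues) - len(residues.lstrip("acgt"))
    wing3 = len(residues) - len(residues.rstrip("acgt"))
    gap = len(residues) - wing5 - wing3
    pattern = GapmerPattern(wing5, gap, wing3, chemistry, backbone, conjugate)
    return residues.upper(), pattern


def pattern_json(aso_sequence: str, pattern: GapmerPattern) -> str:
    """Machine-readable record of sequence + modification pattern."""
    return json.dumps({
        "sequence": aso_sequence.upper(),
        "wing5": pattern.wing5, "gap": pattern.gap, "wing3": pattern.wing3,
        "wing_chemistry": pattern.wing_chemistry,
        "backbone": pattern.backbone, "conjugate": pattern.conjugate,
        "annotation": annotate(aso_sequence, pattern),
    })


def convert_moe_to_cet(candidate: GapmerCandidate) -> GapmerCandidate:
    """Trim a 20-mer 5-10-5 MOE lead to the 16-mer 3-10-3 cEt design.

    Two bases are removed at each end; the central 10-nt gap is untouched
    and the target start shifts by +2. Derived metrics that depend on the
    full 20-mer (MFE, off-targets, homology, tier, rank) are invalidated.
    """
    if len(candidate.aso_sequence) != 20:
        raise DataError(
            f"MOE->cEt conversion needs a 20-mer, got {len(candidate.aso_sequence)}")
    from .candgen import compute_gc, reverse_complement
    site = candidate.target_site[2:18]
    return GapmerCandidate(
        gene_id=candidate.gene_id,
        start=candidate.start + 2,
        window=16,
        target_site=site,
        aso_sequence=reverse_complement(site),
        gc=compute_gc(site),
    )


def extend_cet_to_moe(candidate: GapmerCandidate, flank5: str, flank3: str
                      ) -> GapmerCandidate:
    """Inverse conversion: extend a 16-mer 3-10-3 site by the two flanking
    target bases on each side, giving the 20-mer 5-10-5 comparator."""
    if len(candidate.target_site) != 16:
        raise DataError(
            f"cEt->MOE extension needs a 16-mer, got {len(candidate.target_site)}")
    if len(flank5) != 2 or len(flank3) != 2:
        raise DataError("flanking target bases must be 2 nt on each side")
    from .candgen import compute_gc, reverse_complement
    site = (flank5 + candidate.target_site + flank3).upper()
    return GapmerCandidate(
        gene_id=candidate.gene_id,
        start=candidate.start - 2,
        window=20,
        target_site=site,
        aso_sequence=reverse_complement(site),
        gc=compute_gc(site),
    )
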
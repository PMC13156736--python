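"""Intrinsic secondary-structure stability of the candidate oligo.

A Zuker-style dynamic program over nearest-neighbor stack energies with
hairpin, bulge and internal-loop penalties. Multibranch loops are excluded:
a 20-mer cannot meaningfully form a multiloop, and the restricted structure
class admits an exact exhaustive-enumeration oracle. Energies are handled
as integer tenths of a kcal/mol (0.1 kcal/mol resolution); ties are broken
toward fewer base pairs.

The energy model is data: a shipped TSV of DNA dG37 parameters
(``data/nn_params.tsv``) loadable/replaceable via :func:`load_nn_table`.
Folding is computed on the ASO oligo itself, as DNA — self-structure of
the synthesized strand, not target accessibility.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqio import DataError

logger = logging.getLogger(__name__)

MIN_HAIRPIN_LOOP = 3
MAX_LOOP = 30  # bulge/internal loops above this are disallowed;
               # hairpins above it reuse the size-30 penalty
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_INF = 10 ** 9


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor stack energies and loop penalties (integer tenths)."""

    stack: dict[str, int]          # 5'->3' top dinucleotide -> dG*10
    hairpin: dict[int, int]        # loop size -> penalty*10
    bulge: dict[int, int]
    internal: dict[int, int]
    min_hairpin_loop: int = MIN_HAIRPIN_LOOP

    def hairpin_penalty(self, size: int) -> int:
        """Hairpin-loop penalty; sizes past the table reuse its last entry."""
        return self.hairpin[min(size, max(self.hairpin))]


def load_nn_table(path: str | Path | None = None) -> NNParameterTable:
    """Load a parameter TSV (columns: kind, key, energy in kcal/mol)."""
    if path is None:
        ref = resources.files("gapmerdesign.data") / "nn_params.tsv"
        fh = ref.open()
    else:
        fh = open(path)
    stack: dict[str, int] = {}
    hairpin: dict[int, int] = {}
    bulge: dict[int, int] = {}
    internal: dict[int, int] = {}
    with fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t")
        for row in reader:
            kind, key = row["kind"], row["key"]
            tenths = round(float(row["energy"]) * 10)
            if kind == "stack":
                if tenths > 0:
                    raise DataError(f"stack {key} has positive energy")
                stack[key.upper()] = tenths
            elif kind in ("hairpin", "bulge", "internal"):
                if tenths < 0:
                    raise DataError(f"{kind} loop {key} has negative penalty")
                {"hairpin": hairpin, "bulge": bulge, "internal": internal}[kind][int(key)] = tenths
            else:
                raise DataError(f"unknown parameter kind {kind!r}")
    wc_steps = {a + b for a in "ACGT" for b in "ACGT"}
    missing = wc_steps - set(stack)
    if missing:
        raise DataError(f"parameter table misses stacks: {sorted(missing)}")
    if MIN_HAIRPIN_LOOP not in hairpin:
        raise DataError("parameter table misses the minimal hairpin penalty")
    return NNParameterTable(stack=stack, hairpin=hairpin, bulge=bulge,
                            internal=internal)


_DEFAULT_TABLE: NNParameterTable | None = None


def default_nn_table() -> NNParameterTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_nn_table()
    return _DEFAULT_TABLE


def _pairable(a: str, b: str) -> bool:
    return (a, b) in _WC


def _loop_energy(seq: str, i: int, j: int, k: int, l: int,
                 params: NNParameterTable) -> int | None:
    """Energy (tenths) of the loop closed by (i,j) with inner pair (k,l)."""
    b1, b2 = k - i - 1, j - l - 1
    if b1 == 0 and b2 == 0:
        return params.stack[seq[i] + seq[i + 1]]
    size = b1 + b2
    if size > MAX_LOOP:
        return None
    if b1 == 0 or b2 == 0:
        return params.bulge.get(size)
    return params.internal.get(size)


def fold_mfe(oligo: str, params: NNParameterTable | None = None) -> float:
    """Minimum free energy (kcal/mol, <= 0) of the oligo's self-structure.

    0.0 exactly when no structure with negative energy exists. Sequences
    shorter than 8 nt return 0.0 with a warning (too short to fold under
    the model); N is rejected.
    """
    seq = oligo.upper()
    if "N" in seq:
        raise DataError("cannot fold a sequence containing N")
    for ch in seq:
        if ch not in "ACGT":
            raise DataError(f"illegal character {ch!r} in oligo")
    n = len(seq)
    if n < 8:
        logger.warning("oligo of length %d too short to fold; MFE = 0.0", n)
        return 0.0
    if params is None:
        params = default_nn_table()

    # V[i][j]: (energy, npairs) of the best structure closed by pair (i,j)
    V = [[None] * n for _ in range(n)]
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not _pairable(seq[i], seq[j]):
                continue
            best = (params.hairpin_penalty(j - i - 1), 1)
            for k in range(i + 1, j - MIN_HAIRPIN_LOOP):
                for l in range(k + MIN_HAIRPIN_LOOP + 1, j):
                    inner = V[k][l]
                    if inner is None:
                        continue
                    loop = _loop_energy(seq, i, j, k, l, params)
                    if loop is None:
                        continue
                    cand = (inner[0] + loop, inner[1] + 1)
                    if cand < best:
                        best = cand
            V[i][j] = best

    # exterior: best over prefixes, any number of stems, empty allowed
    W = [(0, 0)] * (n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        for i in range(0, j - MIN_HAIRPIN_LOOP - 1):
            closed = V[i][j - 1]
            if closed is None:
                continue
            cand = (W[i][0] + closed[0], W[i][1] + closed[1])
            if cand < best:
                best = cand
        W[j] = best
    mfe_tenths = min(0, W[n][0])
    return mfe_tenths / 10.0


def structure_flag(mfe: float, favorable: float = -2.0,
                   unfavorable: float = -5.0) -> str:
    """Tier flag for the MFE: strictly above -2 favorable, strictly below
    -5 unfavorable, boundaries included in neutral."""
    if mfe > favorable:
        return "favorable"
    if mfe < unfavorable:
        return "unfavorable_structure"
    return "neutral"
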
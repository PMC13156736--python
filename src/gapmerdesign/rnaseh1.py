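"""RNase H1 cleavage-preference scoring from a position-weight table.

The score is the mean, over the scored region of the target site, of a
per-(position, base) weight in [0, 1]; lower score = higher predicted
cleavage efficiency. By default the scored region is the central 10 nt of
the 20-nt site — the stretch complementary to the DNA gap that recruits
RNase H1 — but the region length is declared by the table itself, so a
full-window table scores all 20 positions.

Two tables ship with the package: a uniform null (all 0.25) and a clearly
synthetic placeholder; a table derived from experimental cleavage data is
user-supplied via the ``rnaseh1_table`` config key.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .candgen import GapmerCandidate
from .seqio import DataError

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class RNaseH1Table:
    """Position x base weight matrix over the scored region."""

    weights: dict[tuple[int, str], float]
    region: int  # number of scored positions

    def weight(self, pos: int, base: str) -> float:
        return self.weights[(pos, base)]

    @property
    def min_weight(self) -> float:
        return min(self.weights.values())

    @property
    def max_weight(self) -> float:
        return max(self.weights.values())


def load_table(path: str | Path | None = None, shipped: str = "placeholder") -> RNaseH1Table:
    """Load a weight table TSV with columns position, A, C, G, T.

    With no path, loads a shipped table: ``"placeholder"`` (synthetic
    weights) or ``"uniform"`` (all 0.25).
    """
    if path is None:
        ref = resources.files("gapmerdesign.data") / f"rnaseh1_{shipped}.tsv"
        fh = ref.open()
    else:
        fh = open(path)
    weights: dict[tuple[int, str], float] = {}
    positions: list[int] = []
    with fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t")
        if reader.fieldnames is None or set(BASES) - set(reader.fieldnames):
            missing = sorted(set(BASES) - set(reader.fieldnames or ()))
            raise DataError(f"weight table misses base column(s): {missing}")
        for row in reader:
            pos = int(row["position"])
            positions.append(pos)
            for base in BASES:
                w = float(row[base])
                if not 0.0 <= w <= 1.0:
                    raise DataError(
                        f"weight {w} at position {pos} base {base} outside [0, 1]")
                weights[(pos, base)] = w
    if positions != list(range(len(positions))) or not positions:
        raise DataError("weight table positions must be 0..region-1")
    return RNaseH1Table(weights=weights, region=len(positions))


def scored_region(site: str, table: RNaseH1Table) -> str:
    """The centered substring of the target site the table scores."""
    window = len(site)
    if table.region > window:
        raise DataError(
            f"table region {table.region} exceeds candidate window {window}")
    offset = (window - table.region) // 2
    return site[offset:offset + table.region]


def score(candidate: GapmerCandidate | str, table: RNaseH1Table) -> float:
    """Mean positional weight over the scored region of the target site."""
    site = candidate if isinstance(candidate, str) else candidate.target_site
    region = scored_region(site.upper(), table)
    try:
        total = sum(table.weight(i, b) for i, b in enumerate(region))
    except KeyError as exc:
        raise DataError(f"no weight for {exc.args[0]} in table") from exc
    return total / table.region


def rnaseh1_flag(value: float, favorable: float = 0.2) -> str:
    """Favorable iff the score is strictly below the threshold."""
    if not 0.0 <= value <= 1.0:
        raise DataError(f"RNase H1 score {value} outside [0, 1]")
    return "favorable" if value < favorable else "not_favorable"
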
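"""Cross-species conservation of candidate target sites.

Identity is ungapped: a 20-mer ASO tolerates no indels in its binding
site, so the reported value is the best match fraction over every
same-length substring of the ortholog (1.0 = the site occurs verbatim).
"""

from __future__ import annotations

import logging

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .candgen import GapmerCandidate
from .config import CANONICAL_SPECIES
from .seqio import DataError, OrthologSet

logger = logging.getLogger(__name__)


def site_identity(site: str, ortholog: str) -> float | None:
    """Max ungapped identity of ``site`` against the ortholog.

    Returns ``None`` (NA) when the ortholog is shorter than the site.
    """
    if not site:
        raise DataError("empty site")
    site, ortholog = site.upper(), ortholog.upper()
    if len(ortholog) < len(site):
        return None
    if site in ortholog:  # exact-match short-circuit
        return 1.0
    site_arr = np.frombuffer(site.encode(), dtype=np.uint8)
    orth_arr = np.frombuffer(ortholog.encode(), dtype=np.uint8)
    windows = sliding_window_view(orth_arr, len(site))
    matches = (windows == site_arr).sum(axis=1)
    return int(matches.max()) / len(site)


def homology_profile(candidate: GapmerCandidate, orthologs: OrthologSet,
                     species: tuple[str, ...] = CANONICAL_SPECIES,
                     ) -> dict[str, float | None]:
    """Per-species identity of the candidate's target site (NA = absent)."""
    profile: dict[str, float | None] = {}
    for sp in species:
        seq = orthologs.get(sp)
        profile[sp] = None if seq is None else site_identity(candidate.target_site, seq)
    return profile


def conserved_in(candidate: GapmerCandidate, species: str,
                 min_identity: float = 1.0) -> bool:
    """True iff the candidate's site is conserved in ``species`` at or above
    ``min_identity``. An absent ortholog (NA) counts as non-conserved."""
    if species not in candidate.homology:
        raise DataError(f"species {species!r} not in the homology profile")
    value = candidate.homology[species]
    if value is None:
        logger.warning("no ortholog for %s: treating candidate at %d as non-conserved",
                       species, candidate.start)
        return False
    return value >= min_identity
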
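"""Codon-level counting: Nei–Gojobori sites and pathway-averaged changes.

These primitives back both the pairwise Ka/Ks stand-in and the per-site
selection counting. Site counts follow NG86: at each codon position the
three alternative nucleotides are classified synonymous/nonsynonymous by
the universal code; mutations that create stop codons are excluded from
both tallies (position denominators stay 3). Differences between two codons
are decomposed into single-nucleotide steps averaged over all shortest
pathways, skipping pathways that pass through a stop codon.
"""

from __future__ import annotations

from functools import lru_cache

from .constants import GENETIC_CODE, NUCLEOTIDES, STOP_CODONS

__all__ = [
    "translate",
    "ng86_site_counts",
    "pathway_counts",
    "is_stop",
]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(codon_seq: str) -> str:
    """Translate an ungapped nucleotide sequence (length multiple of 3)."""
    if len(codon_seq) % 3:
        raise ValueError("codon sequence length is not a multiple of 3")
    aas = []
    for i in range(0, len(codon_seq), 3):
        codon = codon_seq[i : i + 3].upper()
        if codon not in GENETIC_CODE:
            raise ValueError(f"invalid codon {codon!r} at position {i}")
        aas.append(GENETIC_CODE[codon])
    return "".join(aas)


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon.

    Example: TTT (Phe) -> (8/3, 1/3).
    """
    codon = codon.upper()
    if codon not in GENETIC_CODE or is_stop(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    n_sites = 0.0
    s_sites = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if is_stop(alt):
                continue  # stop mutations excluded from both tallies
            if GENETIC_CODE[alt] == aa:
                s_sites += 1.0 / 3.0
            else:
                n_sites += 1.0 / 3.0
    return (n_sites, s_sites)


@lru_cache(maxsize=None)
def pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) changes between two sense codons.

    Averages over all shortest single-nucleotide pathways; pathways passing
    through a stop codon are excluded. If every pathway is blocked by stops
    (possible only for some 2–3-step pairs), stop-crossing pathways are
    admitted as a fallback so the count is always defined.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c not in GENETIC_CODE or is_stop(c):
            raise ValueError(f"not a sense codon: {c!r}")
    n, s, count = _walk(codon_a, codon_b, allow_stops=False)
    if count == 0:
        n, s, count = _walk(codon_a, codon_b, allow_stops=True)
    return (n / count, s / count)


def _walk(a: str, b: str, allow_stops: bool) -> tuple[float, float, int]:
    """(sum N, sum S, pathway count) over complete shortest pathways a -> b.

    Every valid pathway carries equal weight, so the caller's division by
    the pathway count gives the uniform NG86 average; pathways through stop
    intermediates are invalid unless ``allow_stops``.
    """
    if a == b:
        return (0.0, 0.0, 1)
    n_sum = s_sum = 0.0
    count = 0
    for pos in (i for i in range(3) if a[i] != b[i]):
        step = a[:pos] + b[pos] + a[pos + 1 :]
        if is_stop(step) and not allow_stops:
            continue
        syn = 1.0 if (not is_stop(step) and GENETIC_CODE[step] == GENETIC_CODE[a]) else 0.0
        rest_n, rest_s, rest_count = _walk(step, b, allow_stops)
        if rest_count == 0:
            continue
        n_sum += rest_n + (1.0 - syn) * rest_count
        s_sum += rest_s + syn * rest_count
        count += rest_count
    return (n_sum, s_sum, count)
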
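"""Degenerate-codon site-saturation library arithmetic.

Diversity and coverage back-of-envelope statistics for libraries built with
degenerate codons (NNK, NNS, NNN) at a handful of saturated sites: the
theoretical codon- and protein-level diversity, the fraction of variants
carrying at least one stop codon, the fold coverage achieved by a given
transformant count, and Poisson-approximation completeness statistics.

Uniform variant abundance is assumed for the coverage formulas; real
libraries skew, so these are optimistic estimates, matching the customary
back-of-envelope usage (e.g. "2.4e6 transformants cover the 20^3 = 8000
theoretical library >10-fold").
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import exp

from Bio.Seq import Seq

from .exceptions import ValidationError

_DEGENERATE = {"N": "ACGT", "K": "GT", "S": "CG"}

SCHEMES = ("NNK", "NNS", "NNN")


@lru_cache(maxsize=None)
def enumerate_scheme(scheme: str) -> tuple[int, int, int]:
    """Enumerate a degenerate codon: (n_codons, n_amino_acids, n_stop_codons)."""
    if any(ch not in _DEGENERATE for ch in scheme) or len(scheme) != 3:
        raise ValidationError(f"unknown degenerate codon scheme {scheme!r}")
    codons = [
        a + b + c
        for a in _DEGENERATE[scheme[0]]
        for b in _DEGENERATE[scheme[1]]
        for c in _DEGENERATE[scheme[2]]
    ]
    translations = [str(Seq(codon).translate()) for codon in codons]
    amino_acids = {t for t in translations if t != "*"}
    stops = sum(1 for t in translations if t == "*")
    return len(codons), len(amino_acids), stops


@dataclass(frozen=True)
class LibraryDesign:
    """A site-saturation library: number of sites, codon scheme, transformants."""

    n_sites: int
    scheme: str = "NNK"
    transformants: float | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("need n_sites >= 1")
        enumerate_scheme(self.scheme)  # validates
        if self.transformants is not None and self.transformants <= 0:
            raise ValidationError("transformants must be positive")


@dataclass(frozen=True)
class DiversityReport:
    codon_combinations: int
    protein_combinations: int
    stop_containing_fraction: float


@dataclass(frozen=True)
class CoverageReport:
    fold_coverage: float
    expected_fraction_observed: float
    p_complete: float


def theoretical_diversity(design: LibraryDesign) -> DiversityReport:
    """Codon/protein diversity and stop-carrying fraction by enumeration.

    For NNK: 32 codons, 20 amino acids and one stop (TAG) per site, so
    ``n`` sites give 32^n codon and 20^n protein combinations and a
    ``1 - (31/32)^n`` chance of at least one stop.
    """
    codons, aas, stops = enumerate_scheme(design.scheme)
    n = design.n_sites
    return DiversityReport(
        codon_combinations=codons**n,
        protein_combinations=aas**n,
        stop_containing_fraction=1.0 - ((codons - stops) / codons) ** n,
    )


def coverage_stats(design: LibraryDesign, protein_level: bool = True) -> CoverageReport:
    """Fold coverage and Poisson completeness for ``transformants`` clones.

    With N transformants over V equiprobable variants, each variant is seen
    ``Poisson(N/V)`` times, so the expected observed fraction is
    ``1 - exp(-N/V)`` and the probability the library is complete is
    ``(1 - exp(-N/V))^V``.  ``protein_level`` selects V as protein (default,
    the level diversity is usually quoted at) or codon combinations.
    """
    if design.transformants is None:
        raise ValidationError("coverage_stats requires transformants to be set")
    div = theoretical_diversity(design)
    v = div.protein_combinations if protein_level else div.codon_combinations
    n = float(design.transformants)
    frac = 1.0 - exp(-n / v)
    # log-space product avoids underflow for large V
    import math

    p_complete = math.exp(v * math.log(frac)) if frac > 0 else 0.0
    return CoverageReport(
        fold_coverage=n / v,
        expected_fraction_observed=frac,
        p_complete=p_complete,
    )
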
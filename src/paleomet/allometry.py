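"""Allometric scaling of maximal metabolic rate (MMR).

MMR (mLO2 h^-1) scales with body mass M (g) roughly as M**b with a
clade-dependent exponent b.  To compare taxa across clades — and to assign
an exponent to fossils, for which no clade regression exists — the clade
exponents are treated as a tip character and reconciled to a single
phylogenetic exponent: the Brownian-motion root state on the reference
tree.  MMR is then expressed mass-independently as MMR / M**b, in units of
mLO2 h^-1 g^-b.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping

from .phylo import PhyloTree, TreeError, brownian_root_state

__all__ = [
    "DEFAULT_CLADE_EXPONENTS",
    "AllometricModel",
    "phylogenetic_exponent",
    "mass_independent_mmr",
]

#: Literature clade exponents: non-avian sauropsids, synapsids (mammals),
#: and avian sauropsids.  Config-overridable in the pipeline.
DEFAULT_CLADE_EXPONENTS: dict[str, float] = {
    "non_avian_sauropsid": 0.829,
    "synapsid": 0.87,
    "avian": 1.02,
}


@dataclasses.dataclass(frozen=True)
class AllometricModel:
    """Clade exponent map plus the reconciled phylogenetic exponent b.

    Reference units: mass in g, MMR in mLO2 h^-1.
    """

    clade_exponents: Mapping[str, float]
    b: float

    def __post_init__(self) -> None:
        for clade, e in self.clade_exponents.items():
            if not (0.0 < e < 2.0):
                raise ValueError(f"exponent for {clade!r} outside (0, 2): {e}")
        if not (0.0 < self.b < 2.0):
            raise ValueError(f"phylogenetic exponent outside (0, 2): {self.b}")

    @property
    def b_rounded(self) -> float:
        """b at the 2-decimal reporting precision."""
        return round(self.b, 2)


def phylogenetic_exponent(
    tree: PhyloTree,
    clade_exponents: Mapping[str, float],
    tip_clades: Mapping[str, str],
) -> float:
    """Reconcile clade exponents to one tree-wide exponent b.

    Each tip receives its clade's exponent as a tip value; b is the
    maximum-likelihood Brownian root state of that character, so it always
    lies within [min, max] of the clade exponents.
    """
    for clade, e in clade_exponents.items():
        if not (0.0 < e < 2.0):
            raise ValueError(f"exponent for {clade!r} outside (0, 2): {e}")
    labels = tree.tip_labels()
    unmapped = [lab for lab in labels if lab not in tip_clades]
    if unmapped:
        raise TreeError(f"tips without a clade assignment: {unmapped}")
    unknown = sorted({tip_clades[lab] for lab in labels} - set(clade_exponents))
    if unknown:
        raise TreeError(f"clades without an exponent: {unknown}")
    values = {lab: float(clade_exponents[tip_clades[lab]]) for lab in labels}
    return brownian_root_state(tree, values)


def mass_independent_mmr(mmr: float, mass_g: float, b: float) -> float:
    """MMR / mass**b, in mLO2 h^-1 g^-b."""
    if not mmr > 0:
        raise ValueError("MMR must be > 0")
    if not mass_g > 0:
        raise ValueError("body mass must be > 0")
    return mmr / mass_g**b
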
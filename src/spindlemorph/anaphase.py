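"""Anaphase-A accounting and the anaphase A/B partition.

Spermatocyte anaphase A (chromosome-to-pole shortening) is not driven by
kinetochore-microtubule depolymerization alone; three geometric factors
contribute, each computable from closed-form inputs:

* release of metaphase chromosome stretch (drop in the FWHM of the
  cross-sectional-area profile along the spindle axis),
* centrosome reshaping (shortening of the plus-end-to-centriole distance),
* opening of the kinetochore-microtubule attachment angle at constant
  microtubule length L: the axial projection loss L (cos a1 - cos a2).

The anaphase A/B partition splits the total gain in autosome separation
into pole-pole elongation (anaphase B, dPP) and chromosome-to-pole
shortening (anaphase A, 2 x mean dPA).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import DistanceSeries, detect_onset

__all__ = [
    "ContributionBudget",
    "ABPartition",
    "angle_contribution",
    "stretch_contribution",
    "centrosome_contribution",
    "contribution_budget",
    "partition_ab",
]


@dataclass
class ContributionBudget:
    stretch_release: float       # um
    centrosome_reshaping: float  # um
    angle_opening: float         # um
    total_anaphase_A: float      # um
    explained_fraction: float    # (sum of the three) / total


@dataclass
class ABPartition:
    delta_aa: float      # um, total gain in autosome-autosome separation
    anaphase_B: float    # um, pole-pole elongation (dPP)
    anaphase_A: float    # um, 2 x mean pole-autosome shortening
    fraction_B: float
    fraction_A: float


def angle_contribution(length_um: float, alpha1_deg: float,
                       alpha2_deg: float) -> float:
    """Axial-projection loss L (cos a1 - cos a2) when the attachment angle
    opens from a1 to a2 at constant microtubule length L (um)."""
    if length_um <= 0:
        raise ValueError("microtubule length must be > 0")
    if not (0 <= alpha1_deg < 90 and 0 <= alpha2_deg < 90):
        raise ValueError("angles must lie in [0, 90) degrees")
    a1, a2 = np.radians([alpha1_deg, alpha2_deg])
    return float(length_um * (np.cos(a1) - np.cos(a2)))


def stretch_contribution(fwhm_metaphase_um: float, fwhm_anaphase_um: float,
                         factor: float = 2.0) -> float:
    """Pole-ward displacement credited to the loss of chromosome stretch:
    factor x (FWHM_metaphase - FWHM_anaphase).

    The default factor of 2 counts the relaxation on both chromosome
    flanks; factor=1 reports the raw FWHM drop.
    """
    delta = fwhm_metaphase_um - fwhm_anaphase_um
    if delta < 0:
        raise ValueError("anaphase FWHM exceeds metaphase FWHM")
    return factor * delta


def centrosome_contribution(meta_range_um: tuple, ana_range_um: tuple) -> float:
    """Shortening of the plus-end-to-centriole distance: midpoint of the
    metaphase range minus midpoint of the anaphase range (um)."""
    m0, m1 = meta_range_um
    a0, a1 = ana_range_um
    if m0 > m1 or a0 > a1:
        raise ValueError("ranges must be ordered (low, high)")
    return float((m0 + m1) / 2 - (a0 + a1) / 2)


def contribution_budget(stretch_um: float, centrosome_um: float,
                        angle_um: float, total_um: float = 1.0) -> ContributionBudget:
    """Sum the three contributions against the total anaphase-A shortening."""
    if total_um <= 0:
        raise ValueError("total anaphase A must be > 0")
    if min(stretch_um, centrosome_um, angle_um) < 0:
        raise ValueError("contributions must be >= 0")
    s = stretch_um + centrosome_um + angle_um
    return ContributionBudget(stretch_release=stretch_um,
                              centrosome_reshaping=centrosome_um,
                              angle_opening=angle_um,
                              total_anaphase_A=total_um,
                              explained_fraction=s / total_um)


def _plateaus(t, y, onset, tail_frac=0.15):
    finite = np.isfinite(y)
    base = y[:onset + 1][finite[:onset + 1]]
    n_tail = max(2, int(round(tail_frac * len(y))))
    tail = y[-n_tail:][finite[-n_tail:]]
    if len(base) == 0 or len(tail) == 0:
        raise ValueError("plateaus not estimable")
    return float(base.mean()), float(tail.mean())


def partition_ab(d: DistanceSeries) -> ABPartition:
    """Partition the total autosome-separation gain into anaphase B (pole
    elongation) and anaphase A (2 x the mean pole-autosome shortening),
    using metaphase and post-elongation plateau means. The two fractions
    are reported as measured — they are not forced to sum to one."""
    if d.onset_frame is None:
        detect_onset(d, key="aa")
    onset = d.onset_frame
    aa0, aa1 = _plateaus(d.t, d.aa, onset)
    pp0, pp1 = _plateaus(d.t, d.pp, onset)
    delta_aa = aa1 - aa0
    if delta_aa <= 1e-9:  # no measurable separation gain
        return ABPartition(delta_aa=float(delta_aa), anaphase_B=0.0,
                           anaphase_A=0.0, fraction_B=0.0, fraction_A=0.0)
    anaphase_b = pp1 - pp0
    deltas = []
    for key in ("pa1", "pa2"):
        y = getattr(d, key)
        if np.isfinite(y).sum() >= 2:
            p0, p1 = _plateaus(d.t, y, onset)
            deltas.append(p0 - p1)  # positive when shortening
    if not deltas:
        raise ValueError("no pole-autosome curves available")
    anaphase_a = 2.0 * float(np.mean(deltas))
    return ABPartition(delta_aa=float(delta_aa), anaphase_B=float(anaphase_b),
                       anaphase_A=anaphase_a,
                       fraction_B=float(anaphase_b / delta_aa),
                       fraction_A=float(anaphase_a / delta_aa))
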
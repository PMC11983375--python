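"""Accurate-mass lipid annotation for negative-ion SIMS.

Measured centroids are matched against theoretical deprotonated-ion masses of
a lipid reference table within a +/-0.01 m/z window and ranked by ppm error.
The [M-H]- convention used is neutral monoisotopic mass minus 1.007276 Da
(the proton mass; the electron is retained, and the electron-mass subtlety is
below the 2-decimal reporting precision).  Fragment-ion hypotheses cover the
serine head-group loss of PS ([M-H-C3H5O2N]-), the N-acetylhexosamine-H2O
loss ([M-C8H13NO5]-) and the monosaccharide loss ([M-C6H10O5]-) of
glycosphingolipids.  Because PS fragments to a PA-like ion in SIMS, a PA
assignment is withdrawn in favour of the PS fragment whenever a significant
intact PS signal is present 87.0320 Da above it.  Assignments below m/z 900
carry metabolomics reporting confidence level 2; heavier species that may be
fragments of larger gangliosides are level 2/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .peaks import PeakTable

PROTON_MASS = 1.007276

ALLOWED_ELEMENTS = frozenset({"C", "H", "N", "O", "P", "S", "Na", "K"})

#: monoisotopic masses of the most abundant isotope (IUPAC/CODATA values,
#: as tabulated by pyteomics' NIST-derived table)
SERINE_HEADGROUP_LOSS = "C3H5NO2"      # 87.0320 Da


class IonType(str, Enum):
    M_MINUS_H = "[M-H]-"
    PS_FRAGMENT = "[M-H-C3H5O2N]-"
    LOSS_HEXNAC_H2O = "[M-C8H13NO5]-"
    LOSS_HEXOSE = "[M-C6H10O5]-"


#: neutral-loss composition subtracted from the deprotonated ion, per ion type
NEUTRAL_LOSS: dict[IonType, str | None] = {
    IonType.M_MINUS_H: None,
    IonType.PS_FRAGMENT: SERINE_HEADGROUP_LOSS,
    IonType.LOSS_HEXNAC_H2O: "C8H13NO5",
    IonType.LOSS_HEXOSE: "C6H10O5",
}


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid identity: class + carbons:double-bonds shorthand and formula."""

    name: str
    lipid_class: str
    formula: str
    source: str = "user"
    prior: bool = True


@dataclass(frozen=True)
class IonHypothesis:
    species: LipidSpecies
    ion_type: IonType
    theoretical_mz: float

    @classmethod
    def of(cls, species: LipidSpecies, ion_type: IonType = IonType.M_MINUS_H) -> "IonHypothesis":
        return cls(species, ion_type, mz_of(species, ion_type))


@dataclass
class Assignment:
    measured_mz: float
    hypothesis: IonHypothesis
    delta_mz: float
    ppm: float
    confidence: str
    ps_pa_rule_applied: bool = False

    @classmethod
    def of(cls, measured_mz: float, hypothesis: IonHypothesis) -> "Assignment":
        delta = measured_mz - hypothesis.theoretical_mz
        return cls(
            measured_mz=measured_mz,
            hypothesis=hypothesis,
            delta_mz=delta,
            ppm=1e6 * delta / hypothesis.theoretical_mz,
            confidence=confidence_of(measured_mz),
        )


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula into non-negative element counts."""
    try:
        comp = _pmass.Composition(formula=formula)
    except Exception as exc:
        raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc
    bad = set(comp) - ALLOWED_ELEMENTS
    if bad:
        raise ValueError(f"unknown element(s) {sorted(bad)} in formula {formula!r}")
    return dict(comp)


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Sum of most-abundant-isotope masses for a formula over C,H,N,O,P,S,Na,K."""
    comp = parse_formula(formula) if isinstance(formula, str) else formula
    return float(_pmass.calculate_mass(composition=_pmass.Composition(comp)))


def mz_of(species: LipidSpecies, ion_type: IonType = IonType.M_MINUS_H) -> float:
    """Theoretical m/z of an ion hypothesis.

    [M-H]- is monoisotopic(M) - 1.007276; neutral-loss ions additionally
    subtract the loss composition from the deprotonated ion.
    """
    comp = parse_formula(species.formula)
    loss = NEUTRAL_LOSS[IonType(ion_type)]
    if loss is not None:
        loss_comp = parse_formula(loss)
        for el, n in loss_comp.items():
            if comp.get(el, 0) < n:
                raise ValueError(
                    f"loss {loss} exceeds composition of {species.name} ({species.formula})"
                )
            comp[el] -= n
    return monoisotopic_mass(comp) - PROTON_MASS


def printed_mz(mz: float, decimals: int = 2) -> float:
    """Round-half-up to the precision at which SIMS m/z values are reported."""
    scale = 10**decimals
    return math.floor(mz * scale + 0.5) / scale


def confidence_of(measured_mz: float) -> str:
    """Metabolomics reporting confidence: level 2 below m/z 900, level 2/3 at or above."""
    return "level2" if measured_mz < 900.0 else "level2_3"


# ---------------------------------------------------------------------------
# reference table


def load_lipid_table(path=None) -> list[LipidSpecies]:
    """Load the lipid reference table (bundled DLBCL lymph-node set by default)."""
    if path is None:
        src = resources.files("lipidmsi").joinpath("data/lipids.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
        origin = "bundled_table"
    else:
        df = pd.read_csv(path)
        origin = "user"
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            LipidSpecies(
                name=str(rec.name),
                lipid_class=str(rec.lipid_class),
                formula=str(rec.formula),
                source=origin,
                prior=bool(getattr(rec, "prior", True)),
            )
        )
    names = [s.name for s in out]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in lipid table")
    return out


def build_hypotheses(
    species: Iterable[LipidSpecies],
    ion_types: Sequence[IonType] = (IonType.M_MINUS_H,),
) -> list[IonHypothesis]:
    """Expand species into ion hypotheses, skipping impossible neutral losses."""
    out = []
    for sp in species:
        for it in ion_types:
            try:
                out.append(IonHypothesis.of(sp, it))
            except ValueError:
                continue
    return out


# ---------------------------------------------------------------------------
# search and rules


def search(
    measured_mz: float,
    db: Sequence[IonHypothesis],
    window: float = 0.01,
) -> list[Assignment]:
    """All hypotheses within +/-window of the measured m/z, ranked by |ppm|.

    Ties break toward species carrying the biological-plausibility prior flag,
    then toward lower theoretical m/z.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    hits = [
        Assignment.of(measured_mz, h)
        for h in db
        if abs(measured_mz - h.theoretical_mz) <= window
    ]
    hits.sort(
        key=lambda a: (abs(a.ppm), not a.hypothesis.species.prior, a.hypothesis.theoretical_mz)
    )
    return hits


def annotate_peaks(
    table: PeakTable,
    db: Sequence[IonHypothesis],
    window: float = 0.01,
    ps_rule: bool = True,
    ps_threshold: float | None = None,
) -> list[Assignment]:
    """Best assignment per centroid; unmatched centroids are omitted.

    When ``ps_rule`` is set, PA assignments with a significant intact PS
    partner are reinterpreted as PS fragments.  The default significance
    threshold is 1% of the table's base-peak apex intensity.
    """
    assignments = []
    for mz in table.mz_center:
        hits = search(float(mz), db, window)
        if hits:
            assignments.append(hits[0])
    if ps_rule and assignments:
        if ps_threshold is None:
            ps_threshold = 0.01 * float(table.apex_intensity.max())
        assignments = apply_ps_pa_rule(assignments, table, ps_threshold, window)
    return assignments


def apply_ps_pa_rule(
    assignments: list[Assignment],
    peak_table: PeakTable,
    significance_threshold: float,
    window: float = 0.01,
) -> list[Assignment]:
    """Replace PA assignments by PS-fragment hypotheses where justified.

    For each PA assignment at m/z p: if a centroid exists at p + 87.0320
    (+/-window) whose apex intensity exceeds the threshold and which carries an
    intact PS assignment, the PA hypothesis is swapped for that PS species'
    [M-H-C3H5O2N]- fragment.  The number of annotated peaks never changes.
    """
    serine = monoisotopic_mass(SERINE_HEADGROUP_LOSS)
    by_measured = {round(a.measured_mz, 6): a for a in assignments}
    out = []
    for a in assignments:
        sp = a.hypothesis.species
        if sp.lipid_class != "PA" or a.hypothesis.ion_type != IonType.M_MINUS_H:
            out.append(a)
            continue
        target = a.measured_mz + serine
        d = np.abs(peak_table.mz_center - target)
        replaced = False
        for j in np.argsort(d):
            if d[j] > window:
                break
            if peak_table.apex_intensity[j] <= significance_threshold:
                continue
            partner = by_measured.get(round(float(peak_table.mz_center[j]), 6))
            if (
                partner is not None
                and partner.hypothesis.species.lipid_class == "PS"
                and partner.hypothesis.ion_type == IonType.M_MINUS_H
            ):
                frag = IonHypothesis.of(partner.hypothesis.species, IonType.PS_FRAGMENT)
                new = Assignment.of(a.measured_mz, frag)
                new.ps_pa_rule_applied = True
                out.append(new)
                replaced = True
                break
        if not replaced:
            out.append(a)
    return out


# ---------------------------------------------------------------------------
# reporting


class AccuracySummary(NamedTuple):
    mean_abs_ppm: float
    pct_below_5ppm: float


def accuracy_summary(assignments: Sequence[Assignment] | Sequence[float]) -> AccuracySummary:
    """Mean absolute ppm error and the percentage of assignments under 5 ppm."""
    if len(assignments) == 0:
        raise ValueError("no assignments to summarize")
    ppms = np.array(
        [a.ppm if isinstance(a, Assignment) else float(a) for a in assignments], float
    )
    abs_ppm = np.abs(ppms)
    return AccuracySummary(
        mean_abs_ppm=float(abs_ppm.mean()),
        pct_below_5ppm=float(100.0 * (abs_ppm < 5.0).mean()),
    )


def assignments_frame(assignments: Sequence[Assignment]) -> pd.DataFrame:
    """Assignments as a flat table for CSV export."""
    return pd.DataFrame(
        [
            {
                "measured_mz": a.measured_mz,
                "name": a.hypothesis.species.name,
                "lipid_class": a.hypothesis.species.lipid_class,
                "ion_type": a.hypothesis.ion_type.value,
                "theoretical_mz": a.hypothesis.theoretical_mz,
                "delta_mz": a.delta_mz,
                "ppm": a.ppm,
                "confidence": a.confidence,
                "ps_pa_rule_applied": a.ps_pa_rule_applied,
            }
            for a in assignments
        ]
    )
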
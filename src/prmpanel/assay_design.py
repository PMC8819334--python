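"""Rule-based design of parallel-reaction-monitoring (PRM) assays.

Targeted proteomics monitors a protein through one or two proteotypic
peptides (PTPs): tryptic peptides that map uniquely to the protein and
ionize reliably.  This module implements the rule layer of assay design:

* in-silico tryptic digestion (cleave C-terminal to K/R, not before P);
* PTP filtering — uniqueness, length 7–25, mass <= 6000 Da, predicted
  detectability > 0.5, no Met/Cys (oxidation/alkylation-prone), optional
  modification-motif exclusion; at most two peptides per protein;
* precursor charge selection constrained to the instrument scan range
  m/z 350–1250;
* fragment-transition selection from a spectral library: top-k by
  intensity, excluding the short b1–b3/y1–y3 ions;
* retention-time scheduling with a fixed elution window (default 3 min).

Detectability and retention are supplied by a pluggable predictor.  The
bundled :func:`heuristic_predictor` is a transparent, non-learned surrogate
(logistic in length and hydropathy; retention index proportional to GRAVY)
so the rule layer can be exercised without a trained model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .constants import (
    KYTE_DOOLITTLE,
    MONOISOTOPIC_RESIDUE_MASS,
    PROTON_MASS,
    STANDARD_RESIDUES,
    WATER_MONO,
)

PRECURSOR_MZ_RANGE = (350.0, 1250.0)
MIN_PEPTIDE_LENGTH = 7
MAX_PEPTIDE_LENGTH = 25
MAX_PEPTIDE_MASS = 6000.0
MIN_DETECTABILITY = 0.5
MIN_FRAGMENT_ORDINAL = 4  # y1–y3 and b1–b3 are excluded
FORBIDDEN_RESIDUES = frozenset("MC")
CHARGE_PRIORITY = (2, 3, 1)

REJECTION_REASONS = (
    "not_unique",
    "length",
    "mass",
    "detectability",
    "forbidden_residue",
    "no_valid_charge",
    "too_few_transitions",
)


class SequenceFormatError(ValueError):
    """A sequence contains a character outside the 20 standard residues."""


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for ch in sequence:
        if ch not in STANDARD_RESIDUES:
            raise SequenceFormatError(
                f"non-standard residue {ch!r} in sequence {sequence!r}"
            )


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide and the proteins it maps to."""

    sequence: str
    parents: frozenset[str] = frozenset()
    missed_cleavages: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mass(self) -> float:
        return peptide_mass(self.sequence)

    @property
    def is_unique(self) -> bool:
        return len(self.parents) == 1


@dataclass(frozen=True)
class PeptidePrediction:
    """Predicted detectability (probability) and indexed retention time."""

    detectability: float
    irt: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.detectability <= 1.0:
            raise ValueError(f"detectability {self.detectability} outside [0, 1]")


@dataclass(frozen=True)
class Transition:
    series: str  # 'b' or 'y'
    ordinal: int
    charge: int
    mz: float
    rank: int  # 1-based intensity rank within the selected set


@dataclass
class PeptideAssay:
    """A scheduled PRM assay: precursor plus monitored transitions."""

    peptide: Peptide
    precursor_charge: int
    precursor_mz: float
    transitions: list[Transition]
    rt_window: tuple[float, float] | None = None
    detectability: float = float("nan")
    irt: float = float("nan")

    def validate(self, window_width: float | None = None) -> None:
        lo, hi = PRECURSOR_MZ_RANGE
        if not lo <= self.precursor_mz <= hi:
            raise ValueError(f"precursor m/z {self.precursor_mz} outside [{lo}, {hi}]")
        if len(self.transitions) < 3:
            raise ValueError("assay has fewer than 3 transitions")
        for t in self.transitions:
            if t.ordinal < MIN_FRAGMENT_ORDINAL:
                raise ValueError(f"short fragment {t.series}{t.ordinal} in assay")
        if window_width is not None and self.rt_window is not None:
            width = self.rt_window[1] - self.rt_window[0]
            if width - window_width > 1e-9:
                raise ValueError("RT window wider than scheduling width")


@dataclass(frozen=True)
class RejectionRecord:
    """Audit-trail record: the first failing rule for a rejected peptide."""

    peptide: Peptide
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


def digest(sequence: str, max_missed_cleavages: int = 0) -> list[Peptide]:
    """In-silico tryptic digestion.

    Cleaves C-terminal to K or R unless the following residue is P.  Returns
    products in N→C order; with ``max_missed_cleavages = m`` all products
    spanning 0..m internal cleavage sites are included (fully-cleaved
    products first, then 1-missed, etc., each series in N→C order).
    """
    _check_sequence(sequence)
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")

    cut_points = [0]
    for i, ch in enumerate(sequence[:-1]):
        if ch in "KR" and sequence[i + 1] != "P":
            cut_points.append(i + 1)
    cut_points.append(len(sequence))

    peptides: list[Peptide] = []
    n_frag = len(cut_points) - 1
    for m in range(min(max_missed_cleavages, n_frag - 1) + 1):
        for i in range(n_frag - m):
            seq = sequence[cut_points[i] : cut_points[i + m + 1]]
            peptides.append(Peptide(seq, missed_cleavages=m))
    return peptides


def peptide_mass(sequence: str) -> float:
    """Monoisotopic neutral mass: sum of residue masses plus one water."""
    _check_sequence(sequence)
    return sum(MONOISOTOPIC_RESIDUE_MASS[ch] for ch in sequence) + WATER_MONO


def gravy(sequence: str) -> float:
    """Kyte–Doolittle grand average of hydropathy."""
    _check_sequence(sequence)
    return sum(KYTE_DOOLITTLE[ch] for ch in sequence) / len(sequence)


def heuristic_predictor(peptide: Peptide | str) -> PeptidePrediction:
    """Deterministic, non-learned detectability/retention surrogate.

    Detectability is a logistic function of GRAVY and of distance from a
    favourable tryptic length (~12 residues); the retention index is an
    affine map of GRAVY (hydrophobic peptides elute later in reversed-phase
    LC).  This is a documented stand-in, not a trained model: it preserves
    the *shape* of real predictions (values in [0,1], hydrophobicity-ordered
    retention) but carries no spectral information.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    g = gravy(seq)
    score = 1.5 + 0.8 * g - 0.15 * abs(len(seq) - 12)
    detectability = 1.0 / (1.0 + math.exp(-score))
    irt = 50.0 + 25.0 * g
    return PeptidePrediction(detectability=detectability, irt=irt)


Predictor = Callable[[Peptide], PeptidePrediction]


def build_uniqueness_index(proteome: Mapping[str, str]) -> dict[str, set[str]]:
    """Map every fully-cleaved tryptic peptide to its parent accessions."""
    index: dict[str, set[str]] = {}
    for accession, sequence in proteome.items():
        for pep in digest(sequence, 0):
            index.setdefault(pep.sequence, set()).add(accession)
    return index


def filter_ptps(
    peptides: Sequence[Peptide],
    predictor: Predictor,
    uniqueness_index: Mapping[str, set[str]],
    modification_motifs: Iterable[str] = (),
    max_per_protein: int = 2,
) -> tuple[list[tuple[Peptide, PeptidePrediction]], list[RejectionRecord], list[str]]:
    """Apply the proteotypic-peptide rules in fixed order.

    Rule order (first failure recorded): uniqueness, length 7–25, mass
    <= 6000 Da, detectability > 0.5, forbidden residues (M/C plus any
    configured modification motifs).  Per protein at most
    ``max_per_protein`` accepted peptides are kept, ranked by
    detectability.  Returns (accepted with predictions, rejections,
    accessions left without any eligible peptide).
    """
    motifs = tuple(modification_motifs)
    accepted: list[tuple[Peptide, PeptidePrediction]] = []
    rejections: list[RejectionRecord] = []
    seen_parents: set[str] = set()

    for pep in peptides:
        parents = uniqueness_index.get(pep.sequence, set())
        pep = Peptide(pep.sequence, frozenset(parents), pep.missed_cleavages)
        seen_parents.update(parents)
        prediction = predictor(pep)
        if prediction is None:
            raise ValueError(f"predictor returned no prediction for {pep.sequence}")

        reason = None
        if len(parents) != 1:
            reason = "not_unique"
        elif not MIN_PEPTIDE_LENGTH <= pep.length <= MAX_PEPTIDE_LENGTH:
            reason = "length"
        elif pep.mass > MAX_PEPTIDE_MASS:
            reason = "mass"
        elif prediction.detectability <= MIN_DETECTABILITY:
            reason = "detectability"
        elif set(pep.sequence) & FORBIDDEN_RESIDUES or any(
            m in pep.sequence for m in motifs
        ):
            reason = "forbidden_residue"

        if reason is None:
            accepted.append((pep, prediction))
        else:
            rejections.append(RejectionRecord(pep, reason))

    # Keep at most max_per_protein peptides per protein, best detectability
    # first (ties broken by sequence for determinism).
    by_protein: dict[str, list[tuple[Peptide, PeptidePrediction]]] = {}
    for pep, pred in accepted:
        (parent,) = pep.parents
        by_protein.setdefault(parent, []).append((pep, pred))
    kept: list[tuple[Peptide, PeptidePrediction]] = []
    for parent in sorted(by_protein):
        ranked = sorted(
            by_protein[parent], key=lambda pr: (-pr[1].detectability, pr[0].sequence)
        )
        kept.extend(ranked[:max_per_protein])

    uncovered = sorted(seen_parents - set(by_protein))
    return kept, rejections, uncovered


def select_precursor(
    mass: float, charges: Sequence[int] = CHARGE_PRIORITY
) -> tuple[int, float] | None:
    """Choose a precursor charge whose m/z falls in the scan range.

    m/z(z) = (M + z·m_proton)/z.  Among in-range charge states the priority
    is 2+ > 3+ > 1+ — a deterministic proxy for manual inspection of signal
    response, justified by tryptic peptides predominantly ionizing at 2+.
    Returns None when no charge state lands in range.
    """
    lo, hi = PRECURSOR_MZ_RANGE
    for z in charges:
        mz = (mass + z * PROTON_MASS) / z
        if lo <= mz <= hi:
            return z, mz
    return None


def fragment_mz(sequence: str, series: str, ordinal: int, charge: int = 1) -> float:
    """m/z of a b- or y-series fragment ion."""
    _check_sequence(sequence)
    if not 1 <= ordinal < len(sequence):
        raise ValueError(f"ordinal {ordinal} invalid for length {len(sequence)}")
    if series == "b":
        neutral = sum(MONOISOTOPIC_RESIDUE_MASS[ch] for ch in sequence[:ordinal])
    elif series == "y":
        neutral = (
            sum(MONOISOTOPIC_RESIDUE_MASS[ch] for ch in sequence[-ordinal:]) + WATER_MONO
        )
    else:
        raise ValueError(f"unknown ion series {series!r}")
    return (neutral + charge * PROTON_MASS) / charge


@dataclass(frozen=True)
class LibraryFragment:
    series: str
    ordinal: int
    intensity: float
    charge: int = 1


def select_transitions(
    peptide: Peptide | str,
    library: Sequence[LibraryFragment],
    k: int = 3,
) -> list[Transition] | None:
    """Pick the top-k library fragments, excluding b1–b3/y1–y3.

    Fragments are ranked by intensity (descending); ties prefer the higher
    ordinal, then the y series.  Returns None (peptide flagged
    too_few_transitions) when fewer than 3 eligible fragments remain.
    """
    if k < 3:
        raise ValueError("at least 3 transitions are monitored per peptide")
    if not library:
        raise ValueError("empty spectral library entry")
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    eligible = [f for f in library if f.ordinal >= MIN_FRAGMENT_ORDINAL]
    if len(eligible) < 3:
        return None
    eligible.sort(key=lambda f: (-f.intensity, -f.ordinal, f.series != "y"))
    chosen = eligible[:k]
    return [
        Transition(f.series, f.ordinal, f.charge,
                   fragment_mz(seq, f.series, f.ordinal, f.charge), rank=i + 1)
        for i, f in enumerate(chosen)
    ]


def build_schedule(
    assays: Sequence[PeptideAssay],
    rt_minutes: Mapping[str, float],
    width: float = 3.0,
    gradient: tuple[float, float] = (0.0, 60.0),
) -> list[PeptideAssay]:
    """Assign scheduled acquisition windows of fixed width around each RT.

    Windows are [RT − w/2, RT + w/2] clipped to the gradient; assays are
    returned sorted by window start (ties by sequence).
    """
    g0, g1 = gradient
    scheduled: list[PeptideAssay] = []
    for assay in assays:
        rt = rt_minutes.get(assay.peptide.sequence)
        if rt is None or not math.isfinite(rt):
            raise ValueError(f"missing RT prediction for {assay.peptide.sequence}")
        start = max(g0, rt - width / 2.0)
        end = min(g1, rt + width / 2.0)
        assay.rt_window = (start, end)
        scheduled.append(assay)
    scheduled.sort(key=lambda a: (a.rt_window[0], a.peptide.sequence))
    return scheduled


def max_concurrency(windows: Sequence[tuple[float, float]]) -> int:
    """Largest number of simultaneously open scheduling windows."""
    events = sorted(
        [(s, 1) for s, _ in windows] + [(e, -1) for _, e in windows],
        key=lambda ev: (ev[0], ev[1]),  # closings before openings at a tie
    )
    best = cur = 0
    for _, delta in events:
        cur += delta
        best = max(best, cur)
    return best


def design_assays(
    proteome: Mapping[str, str],
    predictor: Predictor = heuristic_predictor,
    library_for: Callable[[Peptide], Sequence[LibraryFragment]] | None = None,
    k_transitions: int = 3,
    window_width: float = 3.0,
    gradient: tuple[float, float] = (0.0, 60.0),
    modification_motifs: Iterable[str] = (),
) -> tuple[list[PeptideAssay], list[RejectionRecord], list[str]]:
    """Full assay-design chain for a protein collection.

    Digest → PTP filter → precursor charge → transitions → RT schedule.
    ``library_for`` supplies a spectral-library entry per peptide; when
    None, all eligible fragments are given equal unit intensity so ranking
    degenerates to the ordinal/series tie-break.
    """
    index = build_uniqueness_index(proteome)
    all_peptides = [
        pep for acc in sorted(proteome) for pep in digest(proteome[acc], 0)
    ]
    # Deduplicate identical sequences while preserving first-seen order.
    seen: set[str] = set()
    unique_peptides = []
    for pep in all_peptides:
        if pep.sequence not in seen:
            seen.add(pep.sequence)
            unique_peptides.append(pep)

    kept, rejections, uncovered = filter_ptps(
        unique_peptides, predictor, index, modification_motifs
    )

    assays: list[PeptideAssay] = []
    rt_map: dict[str, float] = {}
    span = gradient[1] - gradient[0]
    for pep, pred in kept:
        chosen = select_precursor(pep.mass)
        if chosen is None:
            rejections.append(RejectionRecord(pep, "no_valid_charge"))
            continue
        z, mz = chosen
        if library_for is not None:
            lib = library_for(pep)
        else:
            lib = [
                LibraryFragment(series, o, 1.0)
                for series in ("y", "b")
                for o in range(MIN_FRAGMENT_ORDINAL, pep.length)
            ]
        transitions = select_transitions(pep, lib, k_transitions)
        if transitions is None:
            rejections.append(RejectionRecord(pep, "too_few_transitions"))
            continue
        assays.append(
            PeptideAssay(pep, z, mz, transitions,
                         detectability=pred.detectability, irt=pred.irt)
        )
        # Affine map from retention index (roughly [-60, 160]) onto the
        # usable part of the gradient.
        rt_map[pep.sequence] = gradient[0] + span * (
            0.05 + 0.9 * min(max((pred.irt + 60.0) / 220.0, 0.0), 1.0)
        )

    scheduled = build_schedule(assays, rt_map, width=window_width, gradient=gradient)
    for assay in scheduled:
        assay.validate(window_width)
    return scheduled, rejections, uncovered


def write_isolation_list(assays: Sequence[PeptideAssay], path) -> None:
    """Write a Skyline-style isolation list CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["sequence", "protein", "charge", "precursor_mz",
             "window_start", "window_end", "transitions"]
        )
        for a in assays:
            (parent,) = a.peptide.parents
            frags = ";".join(
                f"{t.series}{t.ordinal}^{t.charge}@{t.mz:.4f}" for t in a.transitions
            )
            writer.writerow(
                [a.peptide.sequence, parent, a.precursor_charge,
                 f"{a.precursor_mz:.4f}", f"{a.rt_window[0]:.2f}",
                 f"{a.rt_window[1]:.2f}", frags]
            )


def write_rejection_audit(rejections: Sequence[RejectionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\treason\n")
        for r in rejections:
            fh.write(f"{r.peptide.sequence}\t{r.reason}\n")
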
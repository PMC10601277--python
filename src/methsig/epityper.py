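"""In-silico MALDI-TOF (EpiTYPER-style) methylation assay layer.

Models the T-cleavage reaction used for quantitative bisulfite analysis:
the amplicon is bisulfite converted (every cytosine outside a CpG reads
as thymine; a CpG cytosine stays variable with methylation), transcribed
into RNA from the T7-tagged primer, and cleaved 3' of every uridine.
Each cleavage fragment is a potential "CpG unit": all CpGs on one
fragment are quantified jointly, and a methylated CpG shifts the fragment
mass by +16 Da (a G appears where an A would for the unmethylated state).
A unit is informative when every one of its mass states falls inside the
detectable window and collides with no mass state of another fragment.

The module also checks primer/amplicon design constraints and performs
unit-matrix quality control: removal of units with more than 20% missing
values, k-nearest-neighbour imputation across units, and aggregation of
units to their parent CpG probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqUtils import MeltingTemp
from sklearn.impute import KNNImputer

__all__ = [
    "Primer",
    "AmpliconAssay",
    "Fragment",
    "CpGUnit",
    "DesignReport",
    "bisulfite_and_fragment",
    "assign_cpg_units",
    "check_assay_design",
    "process_unit_matrix",
    "RIBONUCLEOTIDE_MASS",
]

# Average ribonucleotide residue masses (Da); only differences are
# contract-critical (G - A = 16.00 carries the methylation shift).
RIBONUCLEOTIDE_MASS = {"A": 329.21, "C": 305.18, "G": 345.21, "U": 306.17}
TERMINAL_WATER = 18.02
MASS_WINDOW = (1500.0, 7000.0)
COLLISION_TOL = 1.0  # Da

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Primer:
    sequence: str
    tm: float | None = None  # degrees C; nearest-neighbour Tm when None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - _DNA:
            raise ValueError("primer contains non-DNA characters")
        if self.tm is None:
            self.tm = float(MeltingTemp.Tm_NN(self.sequence))


@dataclass
class AmpliconAssay:
    amplicon_id: str
    sequence: str
    primer_fwd: Primer
    primer_rev: Primer
    reaction: str = "T_reverse"  # T7 tag on the reverse primer

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - _DNA:
            raise ValueError("amplicon contains non-DNA characters")
        if self.reaction not in ("T_forward", "T_reverse"):
            raise ValueError("reaction must be 'T_forward' or 'T_reverse'")

    def cpg_positions(self) -> list[int]:
        """Positions of the forward-strand C of each CpG dinucleotide."""
        seq = self.sequence
        return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


@dataclass
class Fragment:
    index: int
    start: int  # transcript coordinate of the fragment 5' end
    sequence: str  # RNA, unmethylated state (CpG site reads A)
    base_mass: float
    cpg_transcript_positions: list[int]
    cpg_genomic_positions: list[int]

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_genomic_positions)

    def mass(self, methylated: int = 0) -> float:
        if not 0 <= methylated <= self.n_cpg:
            raise ValueError("methylated count exceeds member CpGs")
        shift = RIBONUCLEOTIDE_MASS["G"] - RIBONUCLEOTIDE_MASS["A"]
        return self.base_mass + shift * methylated

    def mass_states(self) -> np.ndarray:
        shift = RIBONUCLEOTIDE_MASS["G"] - RIBONUCLEOTIDE_MASS["A"]
        return self.base_mass + shift * np.arange(self.n_cpg + 1)


def _converted_transcript(assay: AmpliconAssay) -> tuple[str, dict[int, int]]:
    """Bisulfite-converted transcript and transcript->genomic CpG map.

    The strand addressed by the reaction is converted (C->T outside CpG;
    the CpG cytosine is variable and rendered in its unmethylated state),
    then the transcript is the RNA reverse complement of that strand.  A
    CpG site therefore reads A when unmethylated and G when methylated.
    """
    strand = assay.sequence if assay.reaction == "T_reverse" else _revcomp(assay.sequence)
    length = len(strand)
    cpg_strand = [i for i in range(length - 1) if strand[i : i + 2] == "CG"]
    converted = strand.replace("C", "T")  # unmethylated state everywhere
    rna_comp = str.maketrans("ATGC", "UACG")
    transcript = converted.translate(rna_comp)[::-1]
    cpg_map: dict[int, int] = {}
    for i in cpg_strand:
        tx_pos = length - 1 - i
        genomic = i if assay.reaction == "T_reverse" else length - 2 - i
        cpg_map[tx_pos] = genomic
    return transcript, cpg_map


def bisulfite_and_fragment(assay: AmpliconAssay) -> list[Fragment]:
    """U-specific cleavage fragments of the converted transcript.

    RNase A cuts 3' of every U; each maximal inter-cleavage run is one
    fragment.  Base masses assume every CpG unmethylated; methylation
    adds the configured G-A mass difference (+16 Da) per member CpG.
    """
    transcript, cpg_map = _converted_transcript(assay)
    boundaries = []
    start = 0
    for j, base in enumerate(transcript):
        if base == "U":
            boundaries.append((start, j + 1))
            start = j + 1
    if start < len(transcript):
        boundaries.append((start, len(transcript)))
    fragments = []
    for idx, (s, e) in enumerate(boundaries):
        seq = transcript[s:e]
        tx_pos = [p for p in range(s, e) if p in cpg_map]
        fragments.append(
            Fragment(
                index=idx,
                start=s,
                sequence=seq,
                base_mass=sum(RIBONUCLEOTIDE_MASS[b] for b in seq) + TERMINAL_WATER,
                cpg_transcript_positions=tx_pos,
                cpg_genomic_positions=sorted(cpg_map[p] for p in tx_pos),
            )
        )
    return fragments


@dataclass
class CpGUnit:
    unit_id: str
    amplicon_id: str
    fragment_index: int
    member_cpgs: list[int]  # genomic positions of the forward-strand C
    base_mass: float
    informative: bool
    reasons: list[str] = field(default_factory=list)


def assign_cpg_units(
    fragments: list[Fragment],
    amplicon_id: str = "amplicon",
    mass_window: tuple[float, float] = MASS_WINDOW,
    collision_tol: float = COLLISION_TOL,
) -> list[CpGUnit]:
    """Derive CpG units from fragments and flag informativeness.

    CpGs sharing a fragment form one unit.  A unit is informative iff all
    of its mass states (base + 16k Da, k = 0..n_CpG) lie inside the
    detectable window and none falls within ``collision_tol`` of any mass
    state of a different fragment (CpG-free fragments still contribute
    their base mass to the collision background).
    """
    lo, hi = mass_window
    units = []
    states = {f.index: f.mass_states() for f in fragments}
    for frag in fragments:
        if frag.n_cpg == 0:
            continue
        reasons = []
        own = states[frag.index]
        if (own < lo).any() or (own > hi).any():
            reasons.append("mass_outside_window")
        collision = False
        for other in fragments:
            if other.index == frag.index:
                continue
            diff = np.abs(own[:, None] - states[other.index][None, :])
            if (diff <= collision_tol).any():
                collision = True
                break
        if collision:
            reasons.append("mass_collision")
        units.append(
            CpGUnit(
                unit_id=f"{amplicon_id}_frag{frag.index}",
                amplicon_id=amplicon_id,
                fragment_index=frag.index,
                member_cpgs=list(frag.cpg_genomic_positions),
                base_mass=frag.base_mass,
                informative=not reasons,
                reasons=reasons,
            )
        )
    return units


@dataclass
class DesignReport:
    passed: bool
    violations: list[str]
    scores: dict[str, float]
    informative_ratio: float


def check_assay_design(
    assay: AmpliconAssay,
    min_len: int = 200,
    max_len: int = 500,
    max_tm_diff: float = 5.0,
    min_informative_ratio: float = 0.7,
    ideal_tm: float = 60.0,
    ideal_primer_len: tuple[int, int] = (22, 25),
) -> DesignReport:
    """Hard assay-design constraints plus soft primer-quality scores.

    Hard: amplicon length 200-500 bp, primer Tm difference <= 5 C, no CpG
    dinucleotide in either primer, informative/total CpG ratio >= 0.7.
    Soft scores (0-1, larger better): primer length in the 22-25 bp ideal
    band, Tm near 60 C, low thymine content, cytosine-rich 3' end.
    """
    violations = []
    n = len(assay.sequence)
    if not min_len <= n <= max_len:
        violations.append(f"amplicon_length_{n}_outside_{min_len}-{max_len}")
    tm_f, tm_r = assay.primer_fwd.tm, assay.primer_rev.tm
    if abs(tm_f - tm_r) > max_tm_diff:
        violations.append("tm_difference_exceeds_tolerance")
    for name, primer in (("fwd", assay.primer_fwd), ("rev", assay.primer_rev)):
        if "CG" in primer.sequence:
            violations.append(f"primer_{name}_contains_CpG")

    fragments = bisulfite_and_fragment(assay)
    units = assign_cpg_units(fragments, assay.amplicon_id)
    total_cpgs = len(assay.cpg_positions())
    informative_cpgs = sum(len(u.member_cpgs) for u in units if u.informative)
    ratio = informative_cpgs / total_cpgs if total_cpgs else 0.0
    if ratio < min_informative_ratio:
        violations.append("informative_cpg_ratio_below_threshold")

    def _len_score(p: Primer) -> float:
        lo, hi = ideal_primer_len
        if lo <= len(p.sequence) <= hi:
            return 1.0
        gap = min(abs(len(p.sequence) - lo), abs(len(p.sequence) - hi))
        return max(0.0, 1.0 - 0.2 * gap)

    scores = {
        "primer_len": (_len_score(assay.primer_fwd) + _len_score(assay.primer_rev)) / 2,
        "tm_closeness": max(
            0.0, 1.0 - (abs(tm_f - ideal_tm) + abs(tm_r - ideal_tm)) / 20.0
        ),
        "low_t_content": 1.0
        - (assay.primer_fwd.sequence + assay.primer_rev.sequence).count("T")
        / (len(assay.primer_fwd.sequence) + len(assay.primer_rev.sequence)),
        "c_rich_3prime": (
            assay.primer_fwd.sequence[-5:].count("C")
            + assay.primer_rev.sequence[-5:].count("C")
        )
        / 10.0,
    }
    return DesignReport(
        passed=not violations,
        violations=violations,
        scores=scores,
        informative_ratio=ratio,
    )


def process_unit_matrix(
    units: pd.DataFrame,
    unit_to_probe: pd.Series | None = None,
    k_neighbors: int = 5,
    max_missing: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Unit-matrix QC: missingness filter, kNN imputation, probe means.

    Units with a missing fraction strictly above ``max_missing`` are
    dropped.  Remaining gaps are filled with the mean of the
    ``k_neighbors`` nearest units (Euclidean distance on pairwise-complete
    sample vectors); observed entries are never altered.  When a
    unit->probe map is given, units are averaged per parent probe.
    """
    vals = units.to_numpy(dtype=float)
    observed = vals[~np.isnan(vals)]
    if ((observed < 0) | (observed > 1)).any():
        raise ValueError("unit values must lie in [0, 1] or be missing")
    frac_missing = units.isna().mean(axis=1)
    clean = units.loc[frac_missing <= max_missing].copy()
    if clean.empty:
        raise ValueError("no units survive the missingness filter")
    if clean.isna().to_numpy().any():
        if len(clean) == 1:
            # no neighbour units exist; fall back to the unit's own mean
            warnings.warn("single unit; imputing with its own mean", stacklevel=2)
            clean = clean.apply(lambda r: r.fillna(r.mean()), axis=1)
        else:
            k = k_neighbors
            if k > len(clean) - 1:
                warnings.warn(
                    f"k_neighbors={k} exceeds available units; "
                    f"using {len(clean) - 1}",
                    stacklevel=2,
                )
                k = len(clean) - 1
            imputer = KNNImputer(n_neighbors=k, keep_empty_features=True)
            clean = pd.DataFrame(
                imputer.fit_transform(clean.to_numpy()),
                index=clean.index,
                columns=clean.columns,
            )
    probe_means = None
    if unit_to_probe is not None:
        parents = unit_to_probe.reindex(clean.index)
        probe_means = clean.groupby(parents).mean()
        probe_means.index.name = "probe_id"
    return clean, probe_means
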
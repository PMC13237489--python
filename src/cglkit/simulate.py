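"""Seeded synthetic-data generators for every pipeline input.

These generators emulate the statistical structure the pipeline assumes —
an imbalanced weakly-labeled homolog family with species metadata, a
planted context-dependent label signal, toy position-specific scoring
matrices, planted-contact trajectories, and noisy Michaelis-Menten
progress curves — so the whole artifact is testable without any download.
Every generator is a pure function of its spec and seed.

The family's ``contextual_pair`` label rule makes the high-activity class
depend on the co-occurrence pattern of two sequence motifs (present-
exactly-one), a relation that is invisible to any linear function of
pooled presence indicators but recoverable by nonlinear models on
residue-level context embeddings.  A third, strictly conserved catalytic
motif is destroyed by the site-knockout penalty variants, which is what
makes the no-activity class learnable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contacts import ContactSpec, TrajectoryFrames
from .embeddings import EmbedderSpec, ResidueEmbedding, synthetic_embed
from .kinetics import (STANDARD_GRID_UM, SUBSTRATE_GRID_MM, ProgressCurve,
                       StandardCurve)
from .model import ActivityLabel
from .mutants import SiteAnnotation, site_knockout_variants
from .prioritize import PSSM_ALPHABET, PSSMatrix
from .seqio import CANONICAL_AA, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FamilySpec",
    "FamilyFixture",
    "generate_family",
    "penalty_records",
    "embed_records",
    "generate_curation_input",
    "generate_pssm",
    "generate_trajectories",
    "default_contact_fixture",
    "generate_progress_curves",
]

# Planted motifs.  The catalytic motif is conserved across the natural
# family; the two signal motifs define the activity label.
CATALYTIC_MOTIF = "YDK"
MOTIF_A = "WCWCW"
MOTIF_B = "FMFMF"

_PATHOGEN_GENERA = ("Mycobacterium", "Xanthomonas", "Staphylococcus",
                    "Klebsiella", "Vibrio")
_BENIGN_GENERA = ("Bacillus", "Lactobacillus", "Streptomyces", "Rhizobium",
                  "Paenibacillus", "Sphingomonas")


@dataclass(frozen=True)
class FamilySpec:
    """Conditions of the synthetic homolog family.

    ``class_ratio`` is the high-activity fraction among natural sequences
    (default emulates the real family's ~8/92 percent split);
    ``label_rule`` is 'contextual_pair' (exactly-one-of-two-motifs) or
    'pooled_motif' (single-motif presence, linearly detectable).
    """

    root_length: int = 96
    n_sequences: int = 600
    substitution_rate: float = 0.05
    class_ratio: float = 916 / 11189
    label_rule: str = "contextual_pair"
    species_per_genus: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must lie in [0, 1)")
        if self.label_rule not in ("contextual_pair", "pooled_motif"):
            raise ValueError(f"unknown label_rule {self.label_rule!r}")


@dataclass
class FamilyFixture:
    records: list[SequenceRecord]
    labels: list[ActivityLabel]
    catalytic_positions: tuple[int, ...]   # 1-based
    spec: FamilySpec


def _scrub(seq: list[str], motifs, protected: set[int],
           rng: np.random.Generator) -> None:
    """Destroy accidental motif occurrences by mutating their center."""
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for motif in motifs:
            start = s.find(motif)
            while start != -1:
                center = start + 1
                if center not in protected:
                    choices = [a for a in CANONICAL_AA if a != seq[center]]
                    seq[center] = choices[rng.integers(len(choices))]
                    changed = True
                start = s.find(motif, start + 1)
                s = "".join(seq)


def generate_family(spec: FamilySpec = FamilySpec()) -> FamilyFixture:
    """Homologs mutated from a random root, with planted label motifs and
    species metadata drawn so grouped-holdout splits are exercisable."""
    rng = np.random.default_rng(spec.seed)
    L = spec.root_length
    aa = np.array(list(CANONICAL_AA))
    root = list(aa[rng.integers(20, size=L)])
    cat_start = L // 2
    cat_pos0 = tuple(range(cat_start, cat_start + len(CATALYTIC_MOTIF)))
    for k, c in enumerate(CATALYTIC_MOTIF):
        root[cat_start + k] = c

    n = spec.n_sequences
    n_high = int(round(spec.class_ratio * n))
    labels = np.array([ActivityLabel.HIGH] * n_high
                      + [ActivityLabel.LOW] * (n - n_high))
    rng.shuffle(labels)

    # species pools: high-activity sequences come from pathogen genera
    def species_name(genus_pool, i):
        genus = genus_pool[i % len(genus_pool)]
        sp = (i // len(genus_pool)) % spec.species_per_genus
        return f"{genus} species{sp}"

    records, out_labels = [], []
    hi_count = lo_count = 0
    motif_len = len(MOTIF_A)
    for i in range(n):
        seq = list(root)
        for pos in range(L):
            if pos in cat_pos0:
                continue
            if rng.random() < spec.substitution_rate:
                choices = [a for a in CANONICAL_AA if a != seq[pos]]
                seq[pos] = choices[rng.integers(len(choices))]
        _scrub(seq, (MOTIF_A, MOTIF_B), set(cat_pos0), rng)

        # choose non-overlapping plant sites away from the catalytic motif
        def plant(motif):
            while True:
                start = int(rng.integers(0, L - motif_len + 1))
                span = set(range(start - 1, start + motif_len + 1))
                if span & set(cat_pos0):
                    continue
                return start
        label = labels[i]
        if spec.label_rule == "contextual_pair":
            if label == ActivityLabel.HIGH:
                motifs = [MOTIF_A, MOTIF_B] if rng.random() < 0.5 else []
            else:
                motifs = [MOTIF_A if rng.random() < 0.5 else MOTIF_B]
        else:   # pooled_motif
            motifs = [MOTIF_A] if label == ActivityLabel.HIGH else []
        used: set[int] = set()
        for motif in motifs:
            while True:
                start = plant(motif)
                span = set(range(start, start + motif_len))
                if not span & used:
                    break
            used |= set(range(start - 1, start + motif_len + 1))
            for k, c in enumerate(motif):
                seq[start + k] = c
        # planting may have created a second accidental occurrence nearby
        _scrub(seq, [m for m in (MOTIF_A, MOTIF_B) if m not in motifs],
               set(cat_pos0) | used, rng)

        if label == ActivityLabel.HIGH:
            species = species_name(_PATHOGEN_GENERA, hi_count)
            hi_count += 1
        else:
            species = species_name(_BENIGN_GENERA, lo_count)
            lo_count += 1
        records.append(SequenceRecord(
            record_id=f"syn{i:05d}", sequence="".join(seq), species=species))
        out_labels.append(ActivityLabel(int(label)))
    return FamilyFixture(records=records, labels=out_labels,
                         catalytic_positions=tuple(p + 1 for p in cat_pos0),
                         spec=spec)


def penalty_records(fixture: FamilyFixture, n_parents: int = 2
                    ) -> tuple[list[SequenceRecord], list[ActivityLabel]]:
    """Site-saturation knockouts of the catalytic motif in the first
    ``n_parents`` family members, labeled no-activity."""
    recs, labs = [], []
    for parent in fixture.records[:n_parents]:
        sites = SiteAnnotation(parent.record_id, fixture.catalytic_positions)
        for v in site_knockout_variants(parent, sites):
            recs.append(SequenceRecord(
                record_id=f"{parent.record_id}.{v.name}", sequence=v.sequence,
                species=parent.species))
            labs.append(ActivityLabel.NONE)
    return recs, labs


def embed_records(records, embedder: EmbedderSpec) -> list[ResidueEmbedding]:
    return [ResidueEmbedding(sequence_id=r.record_id,
                             matrix=synthetic_embed(r.sequence, embedder).matrix,
                             mask=np.ones(r.length, dtype=bool))
            for r in records]


def generate_curation_input(n_unique: int = 12231, n_duplicates: int = 1408,
                            n_nonmesophilic: int = 1042, n_penalty: int = 1337,
                            seed: int = 0):
    """Synthetic reconstruction of a curation run's bookkeeping.

    Builds ``n_unique`` distinct sequences plus ``n_duplicates`` exact
    copies; exactly ``n_nonmesophilic`` of the unique records carry a genus
    the annotator flags as non-mesophilic.  Returns
    ``(records, annotator, penalty)``.
    """
    from .seqio import MockAnnotator
    rng = np.random.default_rng(seed)

    def uniq_seq(i, prefix="M"):
        # base-20 encoding of i guarantees uniqueness
        s, v = [], i
        for _ in range(7):
            s.append(CANONICAL_AA[v % 20])
            v //= 20
        return prefix + "".join(s)

    records = []
    for i in range(n_unique):
        genus = "Thermus" if i < n_nonmesophilic else "Escherichia"
        records.append(SequenceRecord(
            record_id=f"U{i:05d}", sequence=uniq_seq(i),
            species=f"{genus} strain{i}"))
    for j, i in enumerate(rng.integers(0, n_unique, size=n_duplicates)):
        records.append(SequenceRecord(
            record_id=f"D{j:05d}", sequence=records[i].sequence,
            species=records[i].species))
    penalty = [SequenceRecord(record_id=f"P{i:04d}",
                              sequence=uniq_seq(i, prefix="GG"),
                              species="synthetic knockout")
               for i in range(n_penalty)]
    annotator = MockAnnotator(high_genera=("Mycobacterium",),
                              thermophilic_genera=("Thermus",))
    return records, annotator, penalty


def generate_pssm(parent: SequenceRecord, conservation=None, seed: int = 0,
                  target_mean_delta: float = -6.7,
                  delta_sd: float = 2.5) -> PSSMatrix:
    """Toy PSSM: conserved positions score the wild-type residue high and
    every substitution is penalized so the library-wide mean delta lands
    near ``target_mean_delta``."""
    rng = np.random.default_rng(seed)
    L = parent.length
    if conservation is None:
        conservation = rng.uniform(0.0, 1.0, size=L)
    conservation = np.asarray(conservation, dtype=float)
    if conservation.shape != (L,):
        raise ValueError("conservation profile length must equal parent length")
    scores = np.zeros((L, 20), dtype=int)
    for i, wt in enumerate(parent.sequence):
        wt_score = int(round(2 + 5 * conservation[i]))
        for j, aa in enumerate(PSSM_ALPHABET):
            if aa == wt:
                scores[i, j] = wt_score
            else:
                penalty = rng.normal(-target_mean_delta, delta_sd)
                scores[i, j] = wt_score - int(round(penalty))
    return PSSMatrix(parent_id=parent.record_id, scores=scores,
                     wt_residues=parent.sequence)


# ---------------------------------------------------------------------------
# trajectories

_HELIX_NAMES = {124: "SER", 125: "LEU", 126: "SER", 127: "SER", 128: "VAL",
                129: "VAL", 130: "SER", 131: "SER", 132: "ILE", 133: "PHE",
                134: "SER"}


def generate_trajectories(planted: dict[tuple[int, int], float],
                          n_replicates: int = 5, n_frames: int = 100,
                          system: str = "WT", seed: int = 0,
                          extra_far_residues=(200,),
                          spec: ContactSpec = ContactSpec()
                          ) -> list[TrajectoryFrames]:
    """Planted-contact trajectories.

    ``planted`` maps (helix residue, partner residue) to a per-frame contact
    probability; each frame independently places the partner either in
    contact (0.35 nm from its helix anchor) or just inside the partner
    cutoff (0.55 nm).  Hydrophobic far residues beyond the cutoff and a
    non-hydrophobic near residue exercise the selection rules.
    """
    for q in planted.values():
        if not 0.0 <= q <= 1.0:
            raise ValueError("planted probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, _ = spec.helix_range
    anchors = {p: h for (h, p) in planted}

    def atoms(center):
        offs = np.array([[0.02, 0.0, 0.0], [-0.02, 0.0, 0.0],
                         [0.0, 0.02, 0.0]])
        return center + offs

    trajs = []
    for rep in range(n_replicates):
        resnames = dict(_HELIX_NAMES)
        frames = []
        for _ in range(n_frames):
            frame = {}
            for r, _name in _HELIX_NAMES.items():
                center = np.array([(r - lo) * 0.2, 0.0, 0.0])
                frame[r] = atoms(center)
            for p, h in anchors.items():
                resnames[p] = "LEU"
                q = planted[(h, p)]
                d = 0.35 if rng.random() < q else 0.55
                center = np.array([(h - lo) * 0.2, d, 0.0])
                frame[p] = atoms(center)
            for r in extra_far_residues:
                resnames[r] = "LEU"
                frame[r] = atoms(np.array([0.0, 5.0, float(r)]))
            resnames[300] = "SER"   # near but not hydrophobic: never selected
            frame[300] = atoms(np.array([0.0, -0.3, 0.0]))
            frames.append(frame)
        trajs.append(TrajectoryFrames(system=system, replicate_id=rep,
                                      resnames=resnames, frames=frames))
    return trajs


def default_contact_fixture(seed: int = 0, n_replicates: int = 5,
                            n_frames: int = 100):
    """A wild-type/variant pair of trajectory sets with reduced contact
    probabilities in the variant, emulating loosened hydrophobic packing."""
    wt_probs = {(129, 160): 0.93, (129, 161): 0.45, (125, 117): 0.30,
                (132, 139): 0.55, (133, 166): 0.25}
    mut_probs = {(129, 160): 0.67, (129, 161): 0.35, (125, 117): 0.22,
                 (132, 139): 0.45, (133, 166): 0.18}
    wt = generate_trajectories(wt_probs, n_replicates, n_frames,
                               system="WT", seed=seed)
    mut = generate_trajectories(mut_probs, n_replicates, n_frames,
                                system="V129G", seed=seed + 1)
    return wt, mut


def generate_progress_curves(vmax_um_min: float = 5.0, km_mm: float = 3.0,
                             substrate_grid=SUBSTRATE_GRID_MM,
                             noise_sd_rfu: float = 0.0, seed: int = 0,
                             duration_s: float = 3600.0, dt_s: float = 15.0,
                             slope_rfu_per_um: float = 120.0,
                             intercept_rfu: float = 30.0):
    """Early-phase linear product accumulation at the Michaelis-Menten rate
    per substrate level, plus a matching fluorophore standard curve.

    Returns ``(curves, standard, true_params)`` where ``curves`` maps
    substrate (mM) to a :class:`ProgressCurve`.
    """
    if vmax_um_min <= 0 or km_mm <= 0:
        raise ValueError("kinetic parameters must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    curves = {}
    for s in substrate_grid:
        v = vmax_um_min * s / (km_mm + s)          # uM/min
        conc = v * t / 60.0                         # uM
        rfu = slope_rfu_per_um * conc
        if noise_sd_rfu > 0:
            rfu = rfu + rng.normal(0.0, noise_sd_rfu, size=rfu.shape)
        curves[float(s)] = ProgressCurve(time_s=t, signal_rfu=rfu)
    std_conc = np.array(STANDARD_GRID_UM)
    std_rfu = slope_rfu_per_um * std_conc + intercept_rfu
    if noise_sd_rfu > 0:
        std_rfu = std_rfu + rng.normal(0.0, noise_sd_rfu, size=std_rfu.shape)
    standard = StandardCurve.fit(std_conc, std_rfu)
    return curves, standard, {"vmax": vmax_um_min, "km": km_mm}
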
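"""Mutant prioritization and residue-level attribution.

Single-point mutants are pre-filtered by a conservativeness proxy — the
delta-PSSM, the PSI-BLAST log-odds of the mutant residue minus the
wild-type residue at its position (cutoff -7 by default, chosen near the
library-wide average) — and the survivors are ranked by the ensemble-mean
high-activity probability.  Attribution maps come from integrated gradients
(zero baseline, 50 interpolation steps, target = ensemble-predicted class,
residue score = L2 norm over embedding dimensions) and from incoming
attention (ensemble/block/head-averaged attention with the diagonal zeroed,
summed over source residues).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embeddings import ResidueEmbedding
from .model import ActivityClassifier
from .mutants import Variant

logger = logging.getLogger(__name__)

# Column order of the PSI-BLAST ascii PSSM dialect
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}

__all__ = [
    "PSSM_ALPHABET",
    "PSSMatrix",
    "CandidateRanking",
    "parse_psiblast_pssm",
    "write_ascii_pssm",
    "delta_pssm",
    "prioritize_variants",
    "cutoff_sweep",
    "integrated_gradients",
    "IGResult",
    "incoming_attention",
    "ensemble_incoming_attention",
]


@dataclass(frozen=True)
class PSSMatrix:
    """L x 20 integer log-odds table in the PSI-BLAST column order."""

    parent_id: str
    scores: np.ndarray
    wt_residues: str

    def __post_init__(self):
        if self.scores.shape != (len(self.wt_residues), 20):
            raise ValueError("scores must be L x 20 with L = |wt_residues|")

    def score(self, position: int, aa: str) -> int:
        """Log-odds of ``aa`` at the 1-based ``position``."""
        return int(self.scores[position - 1, _AA_INDEX[aa]])


_ROW_RE = re.compile(r"^\s*(\d+)\s+([A-Z])((?:\s+-?\d+)+)\s*$")


def parse_psiblast_pssm(stream, parent_id: str = "") -> PSSMatrix:
    """Parse the ``-out_ascii_pssm`` dialect (first score block only).

    Header lines and the trailing K/Lambda statistics are ignored; row
    indices must be consecutive from 1.
    """
    text = stream if isinstance(stream, str) else stream.read()
    rows, wt = [], []
    expected = 1
    for line in text.splitlines():
        m = _ROW_RE.match(line)
        if not m:
            continue
        numbers = [int(tok) for tok in m.group(3).split()]
        if len(numbers) < 20:
            continue
        idx = int(m.group(1))
        if idx != expected:
            raise ValueError(
                f"PSSM row index {idx} out of order (expected {expected})")
        expected += 1
        rows.append(numbers[:20])
        wt.append(m.group(2))
    if not rows:
        raise ValueError("no PSSM rows found")
    return PSSMatrix(parent_id=parent_id, scores=np.array(rows, dtype=int),
                     wt_residues="".join(wt))


def write_ascii_pssm(pssm: PSSMatrix, handle) -> None:
    """Write the same ascii dialect the parser reads (round-trip safe)."""
    handle.write("\nLast position-specific scoring matrix computed\n")
    handle.write("            " + "  ".join(PSSM_ALPHABET) + "\n")
    for i, (wt, row) in enumerate(zip(pssm.wt_residues, pssm.scores), start=1):
        cells = " ".join(f"{v:3d}" for v in row)
        handle.write(f"{i:5d} {wt}  {cells}\n")
    handle.write("\n                      K         Lambda\n")


def delta_pssm(pssm: PSSMatrix, variant: Variant) -> int:
    """score(position, mutant) - score(position, wild-type)."""
    pos = variant.position
    if not 1 <= pos <= len(pssm.wt_residues):
        raise ValueError(f"variant position {pos} outside PSSM rows")
    if pssm.wt_residues[pos - 1] != variant.wt_aa:
        raise ValueError(
            f"wild-type mismatch at position {pos}: PSSM has "
            f"{pssm.wt_residues[pos - 1]}, variant claims {variant.wt_aa}")
    return pssm.score(pos, variant.mut_aa) - pssm.score(pos, variant.wt_aa)


@dataclass
class CandidateRanking:
    """Filtered, ensemble-scored ranking of a mutant library."""

    table: pd.DataFrame          # variant, position, delta_pssm, ensemble_p_high,
                                 # passed_filter, rank (dense over passing rows)
    cutoff: float
    library_mean_delta: float

    def passing(self) -> pd.DataFrame:
        return self.table[self.table.passed_filter]


def prioritize_variants(library: list[Variant], pssm: PSSMatrix,
                        p_high: dict[str, float],
                        cutoff: float = -7.0) -> CandidateRanking:
    """Filter by delta-PSSM >= cutoff, rank survivors by ensemble P(high).

    Ties are broken by delta-PSSM (descending) then variant name; rows that
    fail the filter are retained with ``passed_filter`` false and no rank.
    """
    rows = []
    for v in library:
        if v.name not in p_high:
            raise ValueError(f"missing ensemble score for variant {v.name}")
        d = delta_pssm(pssm, v)
        rows.append({"variant": v.name, "position": v.position,
                     "delta_pssm": d, "ensemble_p_high": float(p_high[v.name]),
                     "passed_filter": d >= cutoff})
    df = pd.DataFrame(rows)
    df["_name"] = df.variant
    df = df.sort_values(
        by=["passed_filter", "ensemble_p_high", "delta_pssm", "_name"],
        ascending=[False, False, False, True], kind="mergesort",
    ).drop(columns="_name").reset_index(drop=True)
    df["rank"] = pd.array([pd.NA] * len(df), dtype="Int64")
    n_pass = int(df.passed_filter.sum())
    df.loc[:n_pass - 1, "rank"] = np.arange(1, n_pass + 1)
    return CandidateRanking(table=df, cutoff=cutoff,
                            library_mean_delta=float(df.delta_pssm.mean()))


def cutoff_sweep(library: list[Variant], pssm: PSSMatrix,
                 p_high: dict[str, float], cutoffs, top_n: int = 4
                 ) -> pd.DataFrame:
    """Rank stability of the top candidates across delta-PSSM cutoffs."""
    rows = []
    for c in cutoffs:
        r = prioritize_variants(library, pssm, p_high, cutoff=c)
        top = r.passing().variant.head(top_n).tolist()
        rows.append({"cutoff": c, "n_passing": int(r.table.passed_filter.sum()),
                     "top_variants": ",".join(top)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# attribution

@dataclass
class IGResult:
    attributions: np.ndarray    # (L, D), averaged over ensemble members
    ig_scores: np.ndarray       # (L,), L2 norm over embedding dimensions
    target_class: int
    completeness_gap: float     # |sum(attributions) - mean_m (F_m(x)-F_m(0))|


def _target_logit_grad(model: ActivityClassifier, x: np.ndarray,
                       mask: np.ndarray, target: int) -> np.ndarray:
    logits = model.forward(x, mask, train=False)
    d = np.zeros_like(logits)
    d[:, target] = 1.0
    return model.backward(d)


def integrated_gradients(models, embedding: ResidueEmbedding, steps: int = 50,
                         target_class: int | None = None) -> IGResult:
    """Straight-path integrated gradients from the zero embedding.

    The path integral over the target-class logit is evaluated with
    Gauss-Legendre quadrature on [0, 1]; attribution tensors are averaged
    across ensemble members after per-member computation.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    models = list(models)
    x = embedding.matrix[None]                     # (1, L, D)
    mask = embedding.mask[None]
    if target_class is None:
        probs = np.mean([m.predict_proba(x, mask) for m in models], axis=0)
        target_class = int(np.argmax(probs[0]))
    nodes, weights = np.polynomial.legendre.leggauss(steps)
    alphas = (nodes + 1.0) / 2.0
    weights = weights / 2.0
    member_attr = []
    gaps = []
    for m in models:
        integral = np.zeros_like(x)
        for a, w in zip(alphas, weights):
            integral += w * _target_logit_grad(m, a * x, mask, target_class)
        attr = x * integral
        member_attr.append(attr[0])
        f_x = m.forward(x, mask)[0, target_class]
        f_0 = m.forward(np.zeros_like(x), mask)[0, target_class]
        gaps.append(abs(attr.sum() - (f_x - f_0)))
    attributions = np.mean(member_attr, axis=0)
    return IGResult(attributions=attributions,
                    ig_scores=np.linalg.norm(attributions, axis=-1),
                    target_class=target_class,
                    completeness_gap=float(np.mean(gaps)))


def incoming_attention(matrices) -> np.ndarray:
    """Residue-level incoming-attention scores.

    ``matrices`` is any collection of row-stochastic attention tensors of
    shape (..., L, L) (ensemble members x blocks x heads in any nesting).
    All are averaged into a single L x L matrix, the diagonal is zeroed,
    and score_j = sum over i != j of A[i, j].
    """
    flat = []
    for m in matrices:
        m = np.asarray(m)
        if m.shape[-1] != m.shape[-2]:
            raise ValueError("attention matrices must be square")
        flat.append(m.reshape(-1, m.shape[-2], m.shape[-1]))
    if not flat:
        raise ValueError("no attention matrices supplied")
    stacked = np.concatenate(flat, axis=0)
    mean = stacked.mean(axis=0)
    np.fill_diagonal(mean, 0.0)
    return mean.sum(axis=0)


def ensemble_incoming_attention(models, embedding: ResidueEmbedding
                                ) -> np.ndarray:
    """Run inference with attention capture on every ensemble member and
    reduce to the per-residue incoming-attention score."""
    x = embedding.matrix[None]
    mask = embedding.mask[None]
    tensors = []
    for m in models:
        m.forward(x, mask, train=False)
        tensors.extend(m.attention_tensors())
    return incoming_attention(tensors)
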
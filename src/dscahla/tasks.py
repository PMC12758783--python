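"""Downstream procedures: binding-core localization, sequence-logo export
and antibody immunogenicity screening.

Binding-core localization offers three scorers over the candidate start
positions of a peptide (local window *i* corresponds to candidate core
start *i*):

``window`` (default)
    re-score every 9-mer window of the peptide as a peptide in its own
    right against the same allele; the window the model rates most
    presentable is the predicted core.  This directly reuses the trained
    presentation function and localizes reliably even after short training.
``attention``
    the attention mass the peptide-stream query positions inside window
    [i, i+9) assign to local window *i*, averaged over the 9 positions -
    the mechanism-level reading of the cross-attention map.
``feature-norm``
    mean feature norm of the fused peptide rows inside each window.

The immunogenicity screen slides 12-19-mer windows over an antibody chain,
scores every (window, allele) pair against a DRB1 panel, drops cores that
are prevalent in a user-supplied subject table (strictly more than the
threshold) and peptides below a probability cutoff, and reports the number
of unique surviving cores per allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ALPHABET, CORE_LENGTH, HLAAllele, PairExample, PeptideRecord
from .model import Featurizer, PresentationModel

DEFAULT_PANEL = (
    "DRA*01:01-DRB1*01:01",
    "DRA*01:01-DRB1*03:01",
    "DRA*01:01-DRB1*04:01",
    "DRA*01:01-DRB1*07:01",
    "DRA*01:01-DRB1*08:01",
    "DRA*01:01-DRB1*11:01",
    "DRA*01:01-DRB1*13:01",
    "DRA*01:01-DRB1*15:01",
)
DEFAULT_PREVALENCE_THRESHOLD = 22
MIN_WINDOW = 12
MAX_WINDOW = 19


@dataclass
class CorePrediction:
    start: int                       # 0-based offset of the predicted 9-mer core
    core: str
    position_scores: np.ndarray      # one score per candidate start (len = L - 8)

    def __post_init__(self):
        if len(self.core) != CORE_LENGTH:
            raise ValueError("core must be 9 residues")


@dataclass
class PositionFrequencyMatrix:
    counts: np.ndarray               # (9, 21) non-negative ints
    n_sequences: int

    def __post_init__(self):
        if self.counts.shape != (CORE_LENGTH, len(ALPHABET)):
            raise ValueError(f"PFM must be {CORE_LENGTH}x{len(ALPHABET)}")
        if (self.counts.sum(axis=1) != self.n_sequences).any():
            raise ValueError("each PFM row must sum to n_sequences")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=list(ALPHABET),
                            index=[f"P{i + 1}" for i in range(CORE_LENGTH)])

    def information_content(self) -> np.ndarray:
        """Per-position Shannon information (bits) vs a uniform 20-residue background."""
        freq = self.counts / max(self.n_sequences, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(freq > 0, freq * np.log2(freq), 0.0), axis=1)
        return np.log2(20.0) - ent


@dataclass
class ImmunoReport:
    per_allele_core_counts: dict[str, int]
    panel: list[str]
    cutoff: float
    prevalence_threshold: int = DEFAULT_PREVALENCE_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, self.per_allele_core_counts[a]) for a in self.panel],
            columns=["allele", "unique_core_count"])

    @property
    def total_unique_cores(self) -> int:
        return sum(self.per_allele_core_counts.values())


def attention_heatmap_frame(attn: np.ndarray) -> pd.DataFrame:
    """Tabulate one attention map as a CSV-ready heat table.

    Rows are query positions (1-based labels), columns are local windows.
    """
    n_query, n_windows = attn.shape
    return pd.DataFrame(attn,
                        index=[f"pos{q + 1}" for q in range(n_query)],
                        columns=[f"win{w + 1}" for w in range(n_windows)])


# -- core prediction ----------------------------------------------------

def _window_scores_from_attention(attn: np.ndarray, length: int) -> np.ndarray:
    """Average attention mass on window i from query positions [i, i+9)."""
    n_starts = min(length, attn.shape[0]) - CORE_LENGTH + 1
    scores = np.empty(n_starts)
    for i in range(n_starts):
        scores[i] = attn[i:i + CORE_LENGTH, i].mean()
    return scores


def _window_scores_from_features(h_pep: np.ndarray, length: int) -> np.ndarray:
    """Mean feature norm of the fused peptide rows inside each window."""
    norms = np.linalg.norm(h_pep, axis=-1)
    n_starts = min(length, h_pep.shape[0]) - CORE_LENGTH + 1
    return np.array([norms[i:i + CORE_LENGTH].mean() for i in range(n_starts)])


DEFAULT_CORE_SCORER = "window"


def _window_rescore_scores(model: PresentationModel, pairs, registry,
                           featurizer, batch_size: int) -> list[np.ndarray]:
    """Score every 9-mer window of every peptide as its own peptide."""
    l_pep = model.cfg.embedding.l_pep
    sub_pairs: list[PairExample] = []
    owner: list[int] = []
    for idx, pair in enumerate(pairs):
        seq = pair.peptide.sequence
        n_starts = min(len(seq), l_pep) - CORE_LENGTH + 1
        for i in range(n_starts):
            sub_pairs.append(PairExample(
                peptide=PeptideRecord(id=f"{pair.peptide.id}.w{i}",
                                      sequence=seq[i:i + CORE_LENGTH]),
                allele=pair.allele, label=0))
            owner.append(idx)
    probs = model.predict_pairs(sub_pairs, registry, featurizer=featurizer,
                                batch_size=batch_size)
    scores: list[list[float]] = [[] for _ in pairs]
    for idx, p in zip(owner, probs):
        scores[idx].append(float(p))
    return [np.asarray(s) for s in scores]


def predict_cores(model: PresentationModel, pairs: Sequence[PairExample],
                  registry: Mapping[str, HLAAllele],
                  featurizer: Featurizer | None = None,
                  scorer: str = DEFAULT_CORE_SCORER,
                  batch_size: int = 256) -> tuple[np.ndarray, list[CorePrediction]]:
    """Batched presentation scoring plus core localization.

    Returns (probabilities, core predictions).  Ties in the position scores
    break to the leftmost start.
    """
    if scorer not in ("window", "attention", "feature-norm"):
        raise ValueError(f"unknown core scorer {scorer!r}")
    pairs = list(pairs)
    for p in pairs:
        if len(p.peptide) < CORE_LENGTH:
            raise ValueError(f"peptide {p.peptide.id!r} shorter than the 9-mer core")
    featurizer = featurizer or Featurizer(model.cfg)
    model.set_training(False)
    probs_all: list[np.ndarray] = []
    window_scores: list[np.ndarray] = []
    for lo in range(0, len(pairs), batch_size):
        chunk = pairs[lo:lo + batch_size]
        batch = featurizer.prepare(chunk, registry)
        if scorer == "window":
            probs = model.forward(batch)
            probs_all.append(probs.data)
        else:
            probs, out = model.forward(batch, return_attn=True)
            probs_all.append(probs.data)
            for b, pair in enumerate(chunk):
                seq = pair.peptide.sequence
                if scorer == "attention":
                    window_scores.append(
                        _window_scores_from_attention(out.attn_pep.data[b], len(seq)))
                else:
                    window_scores.append(
                        _window_scores_from_features(out.h_pep.data[b], len(seq)))
    if scorer == "window":
        window_scores = _window_rescore_scores(model, pairs, registry,
                                               featurizer, 2 * batch_size)
    cores = []
    for pair, scores in zip(pairs, window_scores):
        start = int(np.argmax(scores))  # argmax is leftmost on ties
        cores.append(CorePrediction(
            start=start, core=pair.peptide.sequence[start:start + CORE_LENGTH],
            position_scores=scores))
    return np.concatenate(probs_all), cores


def predict_core(model: PresentationModel, peptide: PeptideRecord | str,
                 allele: str, registry: Mapping[str, HLAAllele],
                 scorer: str = DEFAULT_CORE_SCORER) -> CorePrediction:
    """Core localization for a single peptide-allele pair."""
    if isinstance(peptide, str):
        peptide = PeptideRecord(id="query", sequence=peptide)
    pair = PairExample(peptide=peptide, allele=allele, label=0)
    _, cores = predict_cores(model, [pair], registry, scorer=scorer)
    return cores[0]


# -- sequence logo ------------------------------------------------------

def build_logo(model: PresentationModel, peptides: Sequence[PeptideRecord],
               allele: str, registry: Mapping[str, HLAAllele],
               top_fraction: float = 0.01, scorer: str = DEFAULT_CORE_SCORER,
               group_by_start: bool = False):
    """Position frequency matrix of predicted cores of the top-scoring peptides.

    Scores all peptides against ``allele``, keeps the top ``top_fraction`` by
    predicted presentation probability, extracts each one's predicted 9-mer
    core and tabulates residue counts per core position.  With
    ``group_by_start`` a separate PFM is returned per predicted start.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    pairs = [PairExample(peptide=p, allele=allele, label=0) for p in peptides]
    probs, cores = predict_cores(model, pairs, registry, scorer=scorer)
    n_keep = int(len(pairs) * top_fraction)
    if n_keep == 0:
        raise ValueError(f"top_fraction {top_fraction} of {len(pairs)} peptides "
                         "selects no peptide")
    keep = np.argsort(-probs, kind="mergesort")[:n_keep]

    def tabulate(indices) -> PositionFrequencyMatrix:
        counts = np.zeros((CORE_LENGTH, len(ALPHABET)), dtype=int)
        for i in indices:
            for pos, aa in enumerate(cores[i].core):
                counts[pos, ALPHABET.index(aa)] += 1
        return PositionFrequencyMatrix(counts=counts, n_sequences=len(indices))

    if not group_by_start:
        return tabulate(keep)
    by_start: dict[int, list[int]] = {}
    for i in keep:
        by_start.setdefault(cores[i].start, []).append(i)
    return {start: tabulate(idx) for start, idx in sorted(by_start.items())}


# -- antibody immunogenicity --------------------------------------------

def enumerate_windows(antibody_seq: str, min_len: int = MIN_WINDOW,
                      max_len: int = MAX_WINDOW) -> list[tuple[int, str]]:
    """All (offset, substring) sliding windows with lengths in [min_len, max_len]."""
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    length = len(antibody_seq)
    windows: list[tuple[int, str]] = []
    for w in range(min_len, max_len + 1):
        for off in range(0, length - w + 1):
            windows.append((off, antibody_seq[off:off + w]))
    return windows


def immunogenicity_screen(model: PresentationModel, antibody_seq: str,
                          registry: Mapping[str, HLAAllele],
                          prevalence_table: Mapping[str, int],
                          panel: Sequence[str] = DEFAULT_PANEL,
                          cutoff: float = 0.5,
                          prevalence_threshold: int = DEFAULT_PREVALENCE_THRESHOLD,
                          scorer: str = DEFAULT_CORE_SCORER) -> ImmunoReport:
    """Count unique presented binding cores of an antibody per panel allele.

    Pipeline: enumerate 12-19-mer windows, score and core-predict every
    (window, allele) pair, drop cores whose subject prevalence is strictly
    greater than ``prevalence_threshold`` (self-like cores), drop peptides
    with presentation probability below ``cutoff``, then count the unique
    surviving cores per allele (pooled over window lengths).
    """
    missing = sorted(set(panel) - set(registry))
    if missing:
        raise KeyError(f"panel allele(s) not in registry: {missing}")
    for core, count in prevalence_table.items():
        if len(core) != CORE_LENGTH or not isinstance(count, (int, np.integer)):
            raise ValueError(f"malformed prevalence entry {core!r}: {count!r}")
    windows = enumerate_windows(antibody_seq)
    if not windows:
        import warnings
        warnings.warn("antibody shorter than the minimum window; nothing to screen")
        return ImmunoReport(per_allele_core_counts={a: 0 for a in panel},
                            panel=list(panel), cutoff=cutoff,
                            prevalence_threshold=prevalence_threshold)
    featurizer = Featurizer(model.cfg)
    counts: dict[str, int] = {}
    for allele in panel:
        pairs = [PairExample(
            peptide=PeptideRecord(id=f"w{off}_{len(seq)}", sequence=seq),
            allele=allele, label=0) for off, seq in windows]
        probs, cores = predict_cores(model, pairs, registry,
                                     featurizer=featurizer, scorer=scorer)
        surviving = {
            c.core for prob, c in zip(probs, cores)
            if prevalence_table.get(c.core, 0) <= prevalence_threshold
            and prob >= cutoff
        }
        counts[allele] = len(surviving)
    return ImmunoReport(per_allele_core_counts=counts, panel=list(panel),
                        cutoff=cutoff, prevalence_threshold=prevalence_threshold)


def load_prevalence_table(path) -> dict[str, int]:
    """Read a core -> subject-count CSV (columns: core, subject_count)."""
    df = pd.read_csv(path, dtype={"core": str})
    if not {"core", "subject_count"} <= set(df.columns):
        raise ValueError("prevalence table needs columns core, subject_count")
    return {row.core: int(row.subject_count) for row in df.itertuples(index=False)}
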
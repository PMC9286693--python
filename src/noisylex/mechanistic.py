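"""Mechanistic measures of online recognition: rank-order competition and
representational similarity analysis (RSA).

All measures probe the network during incremental presentation of one
language's words.  The rank-order measures ask where the target word's
reference pattern falls when all reference patterns are sorted by their
Euclidean distance to the current activation: rank 1 means the target wins
the lexical competition; rank r > 1 means r - 1 spurious words outperform
it.  References are, per layer: the semantic vectors themselves (output
layer), the full phonological vectors (input layer), and the activations
elicited by full phonological forms presented together with their input
semantics (hidden layers PS2 and S4), computed once per trained model in
the clean condition.

RSA builds word-by-word representational dissimilarity matrices (cosine
distance between the activation patterns evoked by each word) per layer,
timestep and noise condition, and Pearson-correlates their strict upper
triangles with reference RDMs computed from the training set's
phonological and semantic representations.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.spatial.distance

from ._util import derive_seed
from .corruption import incremental_input
from .lexicon import BilingualLexicon
from .network import Model, forward

__all__ = [
    "online_accuracy",
    "cumulative_unique_errors",
    "closeness_rank",
    "interlingual_rank",
    "reference_activations",
    "rank_series",
    "build_rdm",
    "rsa_correlate",
    "layer_rdms",
    "rsa_table",
    "MECHANISTIC_LAYERS",
    "MECHANISTIC_NOISE_SD",
]

MECHANISTIC_LAYERS = ("input_phon", "PS2", "S4", "output_sem")
RSA_LAYERS = ("input_phon", "P0", "PS2", "S4", "output_sem")
MECHANISTIC_NOISE_SD = 0.75  # noise level used for the mechanistic contrasts


def closeness_rank(activation: np.ndarray, references: np.ndarray,
                   target_index: int) -> int:
    """Rank of the target's reference among all references by Euclidean
    distance to ``activation`` (1 = closest); ties resolve in lexicon
    order, i.e. a tied earlier-listed word outranks a later one."""
    if not 0 <= target_index < len(references):
        raise ValueError("reference set does not contain the target index")
    d = np.linalg.norm(references - activation, axis=1)
    dt = d[target_index]
    ahead = int(np.sum(d < dt) + np.sum((d == dt)[:target_index]))
    return ahead + 1


def interlingual_rank(activation: np.ndarray, nontarget_references: np.ndarray,
                      translation_index: int) -> int:
    """Rank of the target's translation equivalent within the nontarget
    vocabulary, by distance to the current activation.

    The translation shares the target's semantics but not its phonology,
    so its rank is high at the input layer (weak cross-language
    competition) and drops toward the semantic layers, where the two
    vocabularies converge on shared representations.
    """
    return closeness_rank(activation, nontarget_references, translation_index)


def online_accuracy(ranks: Iterable[int]) -> float:
    """Fraction of words whose output-layer rank is 1 at a timestep."""
    ranks = list(ranks)
    return float(np.mean([r == 1 for r in ranks]))


def cumulative_unique_errors(responses: Sequence[str], target: str) -> list[int]:
    """Cumulative number of distinct erroneous responses over timesteps.

    The count at timestep t covers distinct wrong responses at timesteps
    <= t, and is frozen from the first timestep at which the word is
    correctly recognized onward.
    """
    counts: list[int] = []
    seen: set[str] = set()
    frozen = False
    for resp in responses:
        if not frozen:
            if resp == target:
                frozen = True
            else:
                seen.add(resp)
        counts.append(len(seen))
    return counts


def _target_ranks(queries: np.ndarray, references: np.ndarray) -> np.ndarray:
    """Vectorized :func:`closeness_rank` where query i's target is reference
    i (same word ordering in both sets)."""
    D = scipy.spatial.distance.cdist(queries, references)
    n = D.shape[0]
    dt = D[np.arange(n), np.arange(n)]
    less = (D < dt[:, None]).sum(axis=1)
    cols = np.arange(D.shape[1])
    ties = ((D == dt[:, None]) & (cols[None, :] < np.arange(n)[:, None])).sum(axis=1)
    return less + ties + 1


def _counterpart_ranks(queries: np.ndarray, references: np.ndarray,
                       counterparts: np.ndarray) -> np.ndarray:
    """Rank of each query's designated counterpart reference within the
    (nontarget) reference set, by distance to the current activation."""
    D = scipy.spatial.distance.cdist(queries, references)
    n = D.shape[0]
    dt = D[np.arange(n), counterparts]
    less = (D < dt[:, None]).sum(axis=1)
    cols = np.arange(D.shape[1])
    ties = ((D == dt[:, None]) & (cols[None, :] < counterparts[:, None])).sum(axis=1)
    return less + ties + 1


def reference_activations(model: Model, lexicon: BilingualLexicon,
                          language: str) -> dict[str, np.ndarray]:
    """Per-layer reference patterns for one language's words.

    Output layer: the semantic vectors.  Input layer: the full
    phonological vectors (template only, matching the incremental test
    convention).  Hidden layers PS2 and S4: activations elicited by the
    full phonological form presented together with the input semantics,
    clean.
    """
    phons = lexicon.phon_matrix(language, use_prosody=False, language_unit=None).astype(float)
    sems = lexicon.sem_matrix(language).astype(float)
    acts = forward(model, phons, sems)
    return {
        "input_phon": phons,
        "PS2": acts["PS2"],
        "S4": acts["S4"],
        "output_sem": sems,
    }


def rank_series(
    models: Mapping[str, Sequence[Model]],
    lexicon: BilingualLexicon,
    target_language: str = "B",
    nontarget_language: str | None = None,
    noise_sds: Sequence[float] = (0.0, MECHANISTIC_NOISE_SD),
    timesteps: Sequence[int] = tuple(range(1, 6)),
    repetitions: int = 10,
    layers: Sequence[str] = MECHANISTIC_LAYERS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial ranks (and decoded responses) across layers and timesteps.

    One row per (version, replication, sd, repetition, word, timestep,
    layer, candidate scope).  The intralingual scope ranks the target among
    target-language references; the interlingual scope ranks the nearest
    nontarget-language reference among nontarget references.
    """
    if nontarget_language is None:
        nontarget_language = "A" if target_language == "B" else "B"
    words = lexicon.words(target_language)
    words_n = lexicon.words(nontarget_language)
    pair_to_n = {lx.pair_id: j for j, lx in enumerate(words_n)}
    translations = np.array([pair_to_n[lx.pair_id] for lx in words])
    zero_sem = np.zeros((len(words), lexicon.sem_matrix(target_language).shape[1]))
    rows = []
    for version, reps in models.items():
        for rep_id, model in enumerate(reps):
            refs_t = reference_activations(model, lexicon, target_language)
            refs_n = reference_activations(model, lexicon, nontarget_language)
            for sd in noise_sds:
                for repetition in range(repetitions):
                    for t in timesteps:
                        rng = np.random.default_rng(derive_seed(
                            seed, "mech", version, rep_id, f"{sd:.2f}",
                            repetition, t))
                        batch = np.stack([
                            incremental_input(lx, t, noise_sd=sd, rng=rng)
                            for lx in words
                        ])
                        acts = forward(model, batch, zero_sem)
                        for layer in layers:
                            q = acts[layer]
                            ranks = _target_ranks(q, refs_t[layer])
                            ranks_n = _counterpart_ranks(q, refs_n[layer],
                                                         translations)
                            responses = [None] * len(words)
                            if layer == "output_sem":
                                d = scipy.spatial.distance.cdist(q, refs_t[layer])
                                responses = [words[int(j)].key for j in d.argmin(1)]
                            for i in range(len(words)):
                                rows.append((version, rep_id, repetition, sd,
                                             words[i].key, t, layer,
                                             int(ranks[i]), int(ranks_n[i]),
                                             responses[i]))
    return pd.DataFrame(rows, columns=[
        "version", "replication", "repetition", "sd", "word", "t",
        "layer", "rank", "interlingual_rank", "response",
    ])


# -- RSA -------------------------------------------------------------------

def build_rdm(activations: np.ndarray) -> np.ndarray:
    """Cosine-distance representational dissimilarity matrix.

    Entry (i, j) = 1 - cos(activations[i], activations[j]); symmetric with
    a zero diagonal.  A zero-norm activation is maximally dissimilar to
    everything (entries 1), keeping the matrix well defined.
    """
    X = np.asarray(activations, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    G = (X / safe[:, None]) @ (X / safe[:, None]).T
    D = 1.0 - np.clip(G, -1.0, 1.0)
    D[zero, :] = 1.0
    D[:, zero] = 1.0
    np.fill_diagonal(D, 0.0)
    return D


def rsa_correlate(rdm_a: np.ndarray, rdm_b: np.ndarray) -> float:
    """Pearson correlation over the strict upper triangles of two RDMs
    with identical item ordering.  Returns NaN when either triangle is
    constant (correlation undefined)."""
    a = np.asarray(rdm_a, dtype=float)
    b = np.asarray(rdm_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("RDMs must be square matrices of identical shape")
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    if va.std() == 0 or vb.std() == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def layer_rdms(
    model: Model,
    lexicon: BilingualLexicon,
    target_language: str = "B",
    noise_sd: float = 0.0,
    timesteps: Sequence[int] = tuple(range(1, 6)),
    repetitions: int = 10,
    layers: Sequence[str] = RSA_LAYERS,
    seed: int = 0,
) -> dict[tuple[str, int], np.ndarray]:
    """RDMs per (layer, timestep) for one model and noise condition.

    Under noise the RDM is averaged over fresh noise repetitions.
    """
    words = lexicon.words(target_language)
    zero_sem = np.zeros((len(words), lexicon.sem_matrix(target_language).shape[1]))
    n_reps = repetitions if noise_sd > 0 else 1
    out: dict[tuple[str, int], np.ndarray] = {}
    for t in timesteps:
        acc = {layer: np.zeros((len(words), len(words))) for layer in layers}
        for repetition in range(n_reps):
            rng = np.random.default_rng(derive_seed(seed, "rsa", f"{noise_sd:.2f}",
                                                    repetition, t))
            batch = np.stack([incremental_input(lx, t, noise_sd=noise_sd, rng=rng)
                              for lx in words])
            acts = forward(model, batch, zero_sem)
            for layer in layers:
                acc[layer] += build_rdm(acts[layer])
        for layer in layers:
            out[(layer, t)] = acc[layer] / n_reps
    return out


def rsa_table(
    models: Mapping[str, Sequence[Model]],
    lexicon: BilingualLexicon,
    target_language: str = "B",
    noise_sds: Sequence[float] = (0.0, MECHANISTIC_NOISE_SD),
    timesteps: Sequence[int] = tuple(range(1, 6)),
    repetitions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Pearson correlations of layer RDMs with the phonology and semantics
    reference RDMs, per version, noise condition, layer and timestep,
    averaged over trained replications."""
    ref_phon = build_rdm(lexicon.phon_matrix(target_language, use_prosody=False,
                                             language_unit=None).astype(float))
    ref_sem = build_rdm(lexicon.sem_matrix(target_language).astype(float))
    rows = []
    for version, reps in models.items():
        for rep_id, model in enumerate(reps):
            for sd in noise_sds:
                rdms = layer_rdms(model, lexicon, target_language, sd,
                                  timesteps, repetitions,
                                  seed=derive_seed(seed, version, rep_id))
                for (layer, t), rdm in rdms.items():
                    rows.append((version, rep_id, sd, layer, t,
                                 rsa_correlate(rdm, ref_phon),
                                 rsa_correlate(rdm, ref_sem)))
    return pd.DataFrame(rows, columns=[
        "version", "replication", "sd", "layer", "t", "r_phon", "r_sem",
    ])
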
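"""Simulated word-recognition tasks.

Simulation A (offline identification): trained networks receive full
phonological forms under graded word-initial or word-final Gaussian noise
and their output semantics is decoded with a nearest-neighbour criterion
over the target language's semantic vectors.

Simulation B (online recognition): phonological forms are presented
incrementally (one phoneme per timestep); at each timestep the model
"looks" at whichever of four displayed items (target or onset competitor,
plus three unrelated distractors) has semantics closest to the generated
output semantics.  Looking preferences are the baseline-corrected log
ratio of looks to the critical item over mean looks to the distractors.

The Input-based baseline involves no training: its response is simply the
vocabulary word with the closest matching input phonology.  Because it has
no learning process it is exactly identical across "native"/"non-native"
labels, which is why it cannot capture group effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import derive_seed
from .corruption import NoiseSpec, add_noise, incremental_input
from .lexicon import BilingualLexicon, Lexeme, encode_phonology
from .network import ArchitectureSpec, Model, build_model, finetune, forward, pretrain

__all__ = [
    "identify_word",
    "input_based_identify",
    "train_model_versions",
    "run_offline_experiment",
    "run_offline_input_based",
    "unique_misperceptions",
    "aggregate_unique_misperceptions",
    "DisplaySpec",
    "build_display",
    "build_all_displays",
    "run_online_experiment",
    "looking_preference_series",
    "OFFLINE_NOISE_SDS",
    "ONLINE_NOISE_SDS",
]

OFFLINE_NOISE_SDS = (0.0, 0.30, 0.60, 0.90)
ONLINE_NOISE_SDS = (0.0, 0.30, 0.60)
LOOK_SMOOTHING = 0.5
VERSIONS = ("native", "nonnative")


def _nearest(reference: np.ndarray, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index and Euclidean distance of the nearest reference row per query
    row; ties resolve to the lowest index (lexicon order)."""
    d = np.linalg.norm(queries[:, None, :] - reference[None, :, :], axis=2)
    idx = d.argmin(axis=1)
    return idx, d[np.arange(len(queries)), idx]


def identify_word(model: Model, phon_input: np.ndarray, lexicon: BilingualLexicon,
                  candidate_language: str) -> tuple[Lexeme, float]:
    """Decode the model's output semantics with the nearest-neighbour
    criterion over all words of ``candidate_language``."""
    candidates = lexicon.words(candidate_language)
    if not candidates:
        raise ValueError(f"no candidates in language {candidate_language!r}")
    sems = lexicon.sem_matrix(candidate_language).astype(float)
    out = forward(model, phon_input, np.zeros(model.arch.sem_dim))["output_sem"]
    idx, dist = _nearest(sems, out)
    return candidates[int(idx[0])], float(dist[0])


def input_based_identify(phon_input: np.ndarray, lexicon: BilingualLexicon,
                         candidate_language: str, use_prosody: bool = False,
                         language_unit: str | None = None) -> tuple[Lexeme, float]:
    """Untrained baseline: the candidate whose full phonological vector is
    closest (Euclidean) to the input."""
    candidates = lexicon.words(candidate_language)
    if not candidates:
        raise ValueError(f"no candidates in language {candidate_language!r}")
    phons = lexicon.phon_matrix(candidate_language, use_prosody, language_unit).astype(float)
    q = np.atleast_2d(np.asarray(phon_input, dtype=float))
    idx, dist = _nearest(phons, q)
    return candidates[int(idx[0])], float(dist[0])


# -- exposure: training the two model versions ----------------------------

def train_model_versions(
    lexicon: BilingualLexicon,
    target_language: str = "B",
    n_replications: int = 5,
    arch: ArchitectureSpec | None = None,
    pretrain_epochs: int = 50,
    seed: int = 0,
    **finetune_kwargs,
) -> dict[str, list[Model]]:
    """Train native and non-native versions of the model.

    The native version is exposed to the target language three times as
    often as to the other language (exposure ratio 3:1); the non-native
    version reverses the ratio (1:3).  Both versions see the same total
    number of presentations.  Each replication uses its own derived seed
    for weight initialization and training-order randomness.
    """
    if arch is None:
        arch = ArchitectureSpec()
    ratios = {
        "native": (1.0, 3.0) if target_language == "B" else (3.0, 1.0),
        "nonnative": (3.0, 1.0) if target_language == "B" else (1.0, 3.0),
    }
    out: dict[str, list[Model]] = {}
    for version, ratio in ratios.items():
        models = []
        for rep in range(n_replications):
            s = derive_seed(seed, "train", version, rep)
            m = build_model(ArchitectureSpec(**{**vars(arch), "seed": s}))
            m = pretrain(m, lexicon, epochs=pretrain_epochs, seed=derive_seed(s, "pre"))
            m = finetune(m, lexicon, exposure_ratio=ratio,
                         seed=derive_seed(s, "fine"), **finetune_kwargs)
            models.append(m)
        out[version] = models
    return out


# -- simulation A: offline identification ---------------------------------

def run_offline_experiment(
    models: Mapping[str, Sequence[Model]],
    lexicon: BilingualLexicon,
    target_language: str = "B",
    noise_sds: Sequence[float] = OFFLINE_NOISE_SDS,
    positions: Sequence[str] = ("initial", "final"),
    repetitions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial offline identification run.

    Factors: model version x noise sd x noise position x word x noise
    repetition x trained replication.  Inputs carry the 13-slot template
    and the target-language unit; prosody is off.  Returns one tidy row per
    trial with the decoded response.
    """
    words = lexicon.words(target_language)
    sems = lexicon.sem_matrix(target_language).astype(float)
    clean = np.stack([
        encode_phonology(lx, use_prosody=False, language_unit=target_language)
        for lx in words
    ]).astype(float)
    zero_sem = np.zeros((len(words), sems.shape[1]))
    rows = []
    for version, reps in models.items():
        for rep_id, model in enumerate(reps):
            for sd in noise_sds:
                for position in positions:
                    for repetition in range(repetitions):
                        rng = np.random.default_rng(derive_seed(
                            seed, "offline", version, rep_id, f"{sd:.2f}",
                            position, repetition))
                        spec = NoiseSpec(sd=sd, position=position)
                        batch = np.stack([
                            add_noise(clean[i], words[i], spec, rng)
                            for i in range(len(words))
                        ])
                        out = forward(model, batch, zero_sem)["output_sem"]
                        idx, _ = _nearest(sems, out)
                        for i, lx in enumerate(words):
                            resp = words[int(idx[i])]
                            rows.append((version, rep_id, repetition, sd, position,
                                         lx.key, resp.key, resp.key == lx.key))
    return pd.DataFrame(rows, columns=[
        "version", "replication", "repetition", "sd", "position",
        "target", "response", "correct",
    ])


def run_offline_input_based(
    lexicon: BilingualLexicon,
    target_language: str = "B",
    noise_sds: Sequence[float] = OFFLINE_NOISE_SDS,
    positions: Sequence[str] = ("initial", "final"),
    repetitions: int = 10,
    seed: int = 0,
    versions: Sequence[str] = VERSIONS,
) -> pd.DataFrame:
    """Offline run of the Input-based baseline.  The same trials are
    emitted under every version label: with no training there is nothing
    to differentiate the groups, so the responses are exactly identical."""
    words = lexicon.words(target_language)
    phons = lexicon.phon_matrix(target_language, use_prosody=False,
                                language_unit=target_language).astype(float)
    rows = []
    for sd in noise_sds:
        for position in positions:
            for repetition in range(repetitions):
                rng = np.random.default_rng(derive_seed(
                    seed, "offline-input", f"{sd:.2f}", position, repetition))
                spec = NoiseSpec(sd=sd, position=position)
                batch = np.stack([
                    add_noise(phons[i], words[i], spec, rng)
                    for i in range(len(words))
                ])
                idx, _ = _nearest(phons, batch)
                for i, lx in enumerate(words):
                    resp = words[int(idx[i])]
                    for version in versions:
                        rows.append((version, 0, repetition, sd, position,
                                     lx.key, resp.key, resp.key == lx.key))
    return pd.DataFrame(rows, columns=[
        "version", "replication", "repetition", "sd", "position",
        "target", "response", "correct",
    ])


def unique_misperceptions(responses: Iterable[str], target: str) -> int:
    """Number of distinct erroneous response types across repetitions."""
    return len({r for r in responses if r != target})


def aggregate_unique_misperceptions(trials: pd.DataFrame,
                                    by: Sequence[str] = ("version", "sd", "position"),
                                    ) -> pd.DataFrame:
    """Mean number of unique misperception errors per incorrectly
    identified word, for each condition cell.  Words with zero errors in a
    cell contribute no value to that cell's mean."""
    rows = []
    for keys, g in trials.groupby([*by, "replication", "target"], sort=False):
        target = keys[-1]
        n = unique_misperceptions(g["response"], target)
        rows.append((*keys, n if n > 0 else np.nan))
    per_word = pd.DataFrame(rows, columns=[*by, "replication", "target",
                                           "unique_errors"])
    out = (per_word.groupby(list(by), sort=False)["unique_errors"]
           .mean().rename("mean_unique_errors").reset_index())
    return out


# -- simulation B: displays and the online task ---------------------------

@dataclass(frozen=True)
class DisplaySpec:
    """A four-object display: target, onset competitor, three distractors."""

    target: str
    competitor: str
    distractors: tuple[str, str, str]
    flagged: bool = False  # True when no word shares an initial phoneme

    def __post_init__(self) -> None:
        items = {self.target, self.competitor, *self.distractors}
        if len(items) != 5:
            raise ValueError("display roles must name five distinct items")


def _prefix_len(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def build_display(target: Lexeme, lexicon: BilingualLexicon) -> DisplaySpec:
    """Assign an onset competitor and three unrelated distractors.

    The competitor is the same-language word sharing the longest phoneme
    prefix with the target (ties: smallest phonological Euclidean distance,
    then lexicon order).  If no word shares even one initial phoneme the
    display is flagged and the nearest phonological neighbour is used.
    Distractors are the three words maximizing the sum of their
    phonological and semantic distance ranks from the target/competitor
    pair, so they are maximally unrelated on both dimensions.
    """
    words = lexicon.words(target.language)
    if len(words) < 5:
        raise ValueError("lexicon must have at least 5 same-language words")
    phons = lexicon.phon_matrix(target.language, use_prosody=False,
                                language_unit=None).astype(float)
    sems = lexicon.sem_matrix(target.language).astype(float)
    t_i = next(i for i, lx in enumerate(words) if lx.key == target.key)

    d_phon_t = np.linalg.norm(phons - phons[t_i], axis=1)
    prefixes = np.array([
        _prefix_len(target.sampa, lx.sampa) if i != t_i else -1
        for i, lx in enumerate(words)
    ])
    flagged = prefixes.max() == 0
    if flagged:
        order = sorted((i for i in range(len(words)) if i != t_i),
                       key=lambda i: (d_phon_t[i], i))
    else:
        order = sorted((i for i in range(len(words)) if i != t_i),
                       key=lambda i: (-prefixes[i], d_phon_t[i], i))
    c_i = order[0]

    d_phon = np.minimum(d_phon_t, np.linalg.norm(phons - phons[c_i], axis=1))
    d_sem = np.minimum(np.linalg.norm(sems - sems[t_i], axis=1),
                       np.linalg.norm(sems - sems[c_i], axis=1))
    pool = [i for i in range(len(words)) if i not in (t_i, c_i)]
    # ascending ranks (1 = closest); ties broken by lexicon order
    rank_phon = {i: r + 1 for r, i in enumerate(sorted(pool, key=lambda i: (d_phon[i], i)))}
    rank_sem = {i: r + 1 for r, i in enumerate(sorted(pool, key=lambda i: (d_sem[i], i)))}
    chosen = sorted(pool, key=lambda i: (-(rank_phon[i] + rank_sem[i]), i))[:3]
    return DisplaySpec(
        target=target.key,
        competitor=words[c_i].key,
        distractors=tuple(words[i].key for i in sorted(chosen)),
        flagged=bool(flagged),
    )


def build_all_displays(lexicon: BilingualLexicon, language: str = "B"
                       ) -> dict[str, DisplaySpec]:
    return {lx.key: build_display(lx, lexicon) for lx in lexicon.words(language)}


def run_online_experiment(
    models: Mapping[str, Sequence[Model]],
    lexicon: BilingualLexicon,
    displays: Mapping[str, DisplaySpec] | None = None,
    target_language: str = "B",
    noise_sds: Sequence[float] = ONLINE_NOISE_SDS,
    timesteps: Sequence[int] = tuple(range(6)),
    repetitions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Incremental visual-world simulation.

    For each display condition ("target": critical item is the target
    itself; "competitor": critical item is the onset competitor, target
    absent), at every timestep the model looks at the display item whose
    semantics is closest to the generated output semantics.  Returns one
    tidy row per (version, replication, sd, display type, word, timestep,
    repetition) with the looked-at role.
    """
    if displays is None:
        displays = build_all_displays(lexicon, target_language)
    words = lexicon.words(target_language)
    key_to_idx = {lx.key: i for i, lx in enumerate(words)}
    sems = lexicon.sem_matrix(target_language).astype(float)

    # per display type: (n_words, 4, 300) item semantics; item 0 is critical
    item_sems = {}
    for dtype in ("target", "competitor"):
        arr = np.empty((len(words), 4, sems.shape[1]))
        for i, lx in enumerate(words):
            spec = displays[lx.key]
            crit = spec.target if dtype == "target" else spec.competitor
            ks = [crit, *spec.distractors]
            arr[i] = sems[[key_to_idx[k] for k in ks]]
        item_sems[dtype] = arr

    zero_sem = np.zeros((len(words), sems.shape[1]))
    rows = []
    for version, reps in models.items():
        for rep_id, model in enumerate(reps):
            for sd in noise_sds:
                for repetition in range(repetitions):
                    for t in timesteps:
                        rng = np.random.default_rng(derive_seed(
                            seed, "online", version, rep_id, f"{sd:.2f}",
                            repetition, t))
                        batch = np.stack([
                            incremental_input(lx, t, noise_sd=sd, rng=rng)
                            for lx in words
                        ])
                        out = forward(model, batch, zero_sem)["output_sem"]
                        for dtype, items in item_sems.items():
                            d = np.linalg.norm(items - out[:, None, :], axis=2)
                            look = d.argmin(axis=1)  # 0 = critical
                            for i, lx in enumerate(words):
                                rows.append((version, rep_id, repetition, sd,
                                             dtype, lx.key, t, int(look[i])))
    return pd.DataFrame(rows, columns=[
        "version", "replication", "repetition", "sd", "display_type",
        "word", "t", "look",
    ])


def looking_preference_series(
    looks: pd.DataFrame,
    by: Sequence[str] = ("version", "sd", "display_type"),
    per_item: bool = False,
) -> pd.DataFrame:
    """Baseline-corrected log looking preferences.

    Looks are aggregated over repetitions and replications (and over words
    unless ``per_item``).  The preference ratio uses additive smoothing,
    (looks_critical + 0.5) / (mean distractor looks + 0.5), is
    log-transformed (natural log), and the timestep-0 value is subtracted,
    so L(0) = 0 exactly.
    """
    group = [*by, "word"] if per_item else list(by)

    def _one(g: pd.DataFrame) -> pd.DataFrame:
        out = []
        for t, gt in g.groupby("t", sort=True):
            crit = float((gt["look"] == 0).sum())
            distr = float((gt["look"] != 0).sum()) / 3.0
            ratio = (crit + LOOK_SMOOTHING) / (distr + LOOK_SMOOTHING)
            out.append({"t": t, "looks_critical": crit,
                        "mean_distractor_looks": distr,
                        "log_pref_raw": float(np.log(ratio))})
        df = pd.DataFrame(out)
        base = df.loc[df["t"] == 0, "log_pref_raw"]
        df["log_pref"] = df["log_pref_raw"] - (float(base.iloc[0]) if len(base) else 0.0)
        return df

    pieces = []
    for keys, g in looks.groupby(group, sort=False):
        df = _one(g)
        for k, v in zip(group, keys if isinstance(keys, tuple) else (keys,)):
            df[k] = v
        pieces.append(df)
    return pd.concat(pieces, ignore_index=True)
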
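"""Test-time input construction: graded Gaussian noise on occupied slots,
word-initial vs word-final masking, and incremental presentation.

Noise emulating a degraded speech signal is added only to the feature bits
of template slots actually occupied by the word's phonemes; empty slots,
prosody bits and language bits are never altered.  Noisified inputs are
real-valued and are not clipped — the network consumes real inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lexicon import Lexeme, N_FEATURES, PHON_BITS, encode_phonology, occupied_slots

__all__ = ["NoiseSpec", "add_noise", "masking_split", "incremental_input",
           "load_word_masks"]

POSITIONS = ("whole", "initial", "final")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise of standard deviation ``sd`` (0 = clean) applied to
    the whole word, its word-initial phones, or its word-final phones."""

    sd: float = 0.0
    position: str = "whole"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")


def load_word_masks(path) -> dict[str, list[int]]:
    """Optional per-word masks: TSV of lexeme key and comma-separated
    0-based word-initial phone indices, overriding the default half split."""
    masks: dict[str, list[int]] = {}
    from pathlib import Path
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        key, idxs = line.split("\t")
        masks[key] = sorted(int(i) for i in idxs.split(","))
    return masks


def masking_split(sampa: tuple[str, ...] | Lexeme,
                  initial_override: list[int] | None = None
                  ) -> tuple[list[int], list[int]]:
    """Deterministic partition of a word's phoneme indices into a
    word-initial and a word-final set: the first ceil(k/2) phonemes are
    initial, the last floor(k/2) are final.  Single-phoneme words cannot be
    split."""
    if isinstance(sampa, Lexeme):
        sampa = sampa.sampa
    k = len(sampa)
    if k < 2:
        raise ValueError("cannot split a single-phoneme word into initial and final phones")
    if initial_override is not None:
        initial = sorted(set(initial_override))
        if not initial or any(i < 0 or i >= k for i in initial) or len(initial) >= k:
            raise ValueError(f"invalid per-word mask {initial_override} for {k} phonemes")
        return initial, [i for i in range(k) if i not in initial]
    half = (k + 1) // 2
    return list(range(half)), list(range(half, k))


def _slot_feature_indices(slots: list[int]) -> np.ndarray:
    """Flat bit indices of the 22 feature bits of each given template slot."""
    if not slots:
        return np.array([], dtype=int)
    return np.concatenate([np.arange(s * N_FEATURES, (s + 1) * N_FEATURES) for s in slots])


def target_slot_indices(lexeme: Lexeme, position: str,
                        masks: dict[str, list[int]] | None = None) -> list[int]:
    """Occupied template slots targeted by noise at the given position.
    ``masks`` optionally overrides the default half split per lexeme key."""
    occ = occupied_slots(lexeme)
    if position == "whole":
        return occ
    override = masks.get(lexeme.key) if masks else None
    initial, final = masking_split(lexeme.sampa, initial_override=override)
    chosen = initial if position == "initial" else final
    return [occ[i] for i in chosen]


def add_noise(phon: np.ndarray, lexeme: Lexeme, spec: NoiseSpec,
              rng: np.random.Generator,
              masks: dict[str, list[int]] | None = None) -> np.ndarray:
    """Add i.i.d. Gaussian(0, sd) noise to the feature bits of the targeted
    occupied slots of ``phon``; all other bits are returned unchanged."""
    phon = np.asarray(phon, dtype=float)
    if phon.shape != (PHON_BITS,):
        raise ValueError(f"phon vector must have {PHON_BITS} entries")
    out = phon.copy()
    if spec.sd == 0:
        return out
    bits = _slot_feature_indices(target_slot_indices(lexeme, spec.position, masks))
    out[bits] += rng.normal(0.0, spec.sd, size=bits.size)
    return out


def incremental_input(lexeme: Lexeme, t: int, noise_sd: float = 0.0,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Input after incremental presentation of the first ``t`` phonemes.

    Timestep 0 is the complete absence of phonological input (an all-zero
    vector); at timestep t the slots of phonemes 1..t carry their
    (noisified) features and all later slots are zero.  Prosody and
    language bits are zero throughout — the incremental test regime
    presents the 13-slot template only.  ``t`` beyond the word's length
    clamps to the full form.
    """
    if t < 0:
        raise ValueError("timestep must be non-negative")
    full = encode_phonology(lexeme, use_prosody=False, language_unit=None).astype(float)
    occ = occupied_slots(lexeme)  # in phoneme order
    t = min(t, len(occ))
    hidden = _slot_feature_indices(occ[t:])
    full[hidden] = 0.0
    if noise_sd > 0 and t > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        shown = _slot_feature_indices(occ[:t])
        full[shown] += rng.normal(0.0, noise_sd, size=shown.size)
    return full
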
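"""Bilingual lexicons with slot-based phonology and sparse binary semantics.

Words of two languages (A and B, playing the roles of English and Dutch)
are stored as translation pairs.  Each word is a SAMPA-like phoneme string
partitioned into one or two syllables.  Phonological forms are encoded into
a 292-bit vector: a 13-slot disyllabic template CCCVVCCCVVCCC with 22
binary articulatory features per slot (13 x 22 = 286 bits), plus 2 bits of
thermometer-coded syllabic length (monosyllabic = 01, disyllabic = 11),
2 bits of one-hot syllabic stress, and 2 one-hot language-membership bits.
Semantics are 300-bit sparse binary vectors shared exactly by the two
members of a translation pair.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LexiconError",
    "AlignmentError",
    "Lexeme",
    "BilingualLexicon",
    "load_feature_table",
    "align_to_template",
    "encode_phonology",
    "binarize_embedding",
    "generate_synthetic_lexicon",
    "load_lexicon",
    "save_lexicon",
    "export_vectors",
    "apply_real_embeddings",
    "PHON_BITS",
    "SEM_BITS",
    "N_SLOTS",
    "N_FEATURES",
]

# 13-slot template: indices of consonant and vowel slots (0-based).
N_SLOTS = 13
N_FEATURES = 22
SLOT_IS_VOWEL = [False] * 3 + [True] * 2 + [False] * 3 + [True] * 2 + [False] * 3
PHON_BITS = N_SLOTS * N_FEATURES + 6  # 286 feature bits + length + stress + language
SEM_BITS = 300
LENGTH_OFFSET = N_SLOTS * N_FEATURES
STRESS_OFFSET = LENGTH_OFFSET + 2
LANGUAGE_OFFSET = STRESS_OFFSET + 2

# Height bits (columns 14-17) are set for vowels only; used to classify C vs V.
_VOWEL_COLUMNS = slice(14, 18)


class LexiconError(ValueError):
    """Malformed lexicon content."""


class AlignmentError(LexiconError):
    """A syllable does not fit the 13-slot template."""


def load_feature_table() -> dict[str, np.ndarray]:
    """Load the phoneme feature table shipped with the package.

    Returns a mapping from phoneme symbol to a 22-entry uint8 feature row.
    Rows are pairwise distinct (checked).
    """
    ref = importlib.resources.files("noisylex") / "data" / "phoneme_features.tsv"
    lines = ref.read_text(encoding="utf-8").strip().splitlines()
    header = lines[0].split("\t")
    if len(header) != N_FEATURES + 1:
        raise LexiconError(f"feature table must have {N_FEATURES} feature columns")
    table: dict[str, np.ndarray] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        symbol = parts[0]
        row = np.array([int(x) for x in parts[1:]], dtype=np.uint8)
        if row.size != N_FEATURES:
            raise LexiconError(f"bad feature row for phoneme {symbol!r}")
        table[symbol] = row
    rows = {tuple(v) for v in table.values()}
    if len(rows) != len(table):
        raise LexiconError("feature table rows are not pairwise distinct")
    return table


_FEATURE_TABLE = load_feature_table()


def is_vowel(symbol: str) -> bool:
    """True if the phoneme carries a vowel-height feature."""
    try:
        row = _FEATURE_TABLE[symbol]
    except KeyError:
        raise LexiconError(f"unknown phoneme symbol {symbol!r}") from None
    return bool(row[_VOWEL_COLUMNS].any())


@dataclass(frozen=True)
class Lexeme:
    """One word of one language: phonology, prosody and translation-pair id."""

    orthography: str
    language: str  # "A" or "B"
    syllables: tuple[tuple[str, ...], ...]
    stress: int  # 1-based index of the stressed syllable
    pair_id: int

    def __post_init__(self) -> None:
        if self.language not in ("A", "B"):
            raise LexiconError(f"language must be 'A' or 'B', got {self.language!r}")
        if not 1 <= len(self.syllables) <= 2:
            raise LexiconError(
                f"{self.orthography!r}: only monosyllabic and disyllabic words "
                f"are supported, got {len(self.syllables)} syllables"
            )
        if not 1 <= self.stress <= len(self.syllables):
            raise LexiconError(
                f"{self.orthography!r}: stress index {self.stress} exceeds "
                f"syllable count {len(self.syllables)}"
            )
        for syl in self.syllables:
            for ph in syl:
                if ph not in _FEATURE_TABLE:
                    raise LexiconError(
                        f"{self.orthography!r}: unknown phoneme symbol {ph!r}"
                    )

    @property
    def sampa(self) -> tuple[str, ...]:
        """Flat phoneme sequence."""
        return tuple(ph for syl in self.syllables for ph in syl)

    @property
    def key(self) -> str:
        return f"{self.language}:{self.orthography}"

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)


def _split_syllable(syl: Sequence[str], which: int) -> tuple[list[str], list[str], list[str]]:
    """Split one syllable into onset / nucleus / coda; nucleus must be a
    contiguous run of at most two vowels."""
    vowel_flags = [is_vowel(ph) for ph in syl]
    if not any(vowel_flags):
        raise AlignmentError(f"syllable {which}: no vowel in {tuple(syl)}")
    first = vowel_flags.index(True)
    last = len(vowel_flags) - 1 - vowel_flags[::-1].index(True)
    if any(not v for v in vowel_flags[first : last + 1]):
        raise AlignmentError(f"syllable {which}: non-contiguous vowels in {tuple(syl)}")
    onset, nucleus, coda = list(syl[:first]), list(syl[first : last + 1]), list(syl[last + 1 :])
    if len(nucleus) > 2:
        raise AlignmentError(f"syllable {which}: more than 2 vowels in {tuple(syl)}")
    return onset, nucleus, coda


def align_to_template(syllables: Sequence[Sequence[str]]) -> list[str | None]:
    """Left-align a one- or two-syllable phoneme sequence into the 13-slot
    CCCVVCCCVVCCC template.

    Syllable 1 occupies slots 1-8: onset consonants left-aligned in slots
    1-3, vowels in slots 4-5, coda consonants in slots 6-8.  Syllable 2's
    onset consonants left-align into whatever of slots 6-8 the first
    syllable's coda leaves free; its vowels go to slots 9-10 and its coda to
    slots 11-13.  Returns 13 entries, phoneme symbol or ``None`` for empty.
    """
    if not 1 <= len(syllables) <= 2:
        raise AlignmentError(f"expected 1 or 2 syllables, got {len(syllables)}")
    slots: list[str | None] = [None] * N_SLOTS

    onset1, nucleus1, coda1 = _split_syllable(syllables[0], 1)
    if len(onset1) > 3:
        raise AlignmentError(f"syllable 1: onset {tuple(onset1)} exceeds 3 consonant slots")
    if len(coda1) > 3:
        raise AlignmentError(f"syllable 1: coda {tuple(coda1)} exceeds 3 consonant slots")
    for i, ph in enumerate(onset1):
        slots[i] = ph
    for i, ph in enumerate(nucleus1):
        slots[3 + i] = ph
    for i, ph in enumerate(coda1):
        slots[5 + i] = ph

    if len(syllables) == 2:
        onset2, nucleus2, coda2 = _split_syllable(syllables[1], 2)
        free = 3 - len(coda1)  # shared C slots 6-8
        if len(onset2) > free:
            raise AlignmentError(
                f"syllable 2: onset {tuple(onset2)} does not fit the "
                f"{free} consonant slots left by syllable 1's coda"
            )
        if len(coda2) > 3:
            raise AlignmentError(f"syllable 2: coda {tuple(coda2)} exceeds 3 consonant slots")
        for i, ph in enumerate(onset2):
            slots[5 + len(coda1) + i] = ph
        for i, ph in enumerate(nucleus2):
            slots[8 + i] = ph
        for i, ph in enumerate(coda2):
            slots[10 + i] = ph
    return slots


def format_alignment(slots: Sequence[str | None]) -> str:
    """Render a slot assignment as a readable string, '_' for empty slots."""
    return " ".join(ph if ph is not None else "_" for ph in slots)


def encode_phonology(
    lexeme: Lexeme,
    use_prosody: bool = True,
    language_unit: str | None = "own",
) -> np.ndarray:
    """Encode a lexeme into its 292-bit phonological vector.

    Parameters
    ----------
    use_prosody
        When off, the syllabic-length and stress bits are zeroed (the test
        regimes present the 13-slot template only).
    language_unit
        ``"own"`` sets the one-hot language bit of the lexeme's language;
        ``"A"``/``"B"`` force a language; ``None`` zeroes both bits.
    """
    slots = align_to_template(lexeme.syllables)
    vec = np.zeros(PHON_BITS, dtype=np.uint8)
    for s, ph in enumerate(slots):
        if ph is not None:
            vec[s * N_FEATURES : (s + 1) * N_FEATURES] = _FEATURE_TABLE[ph]
    if use_prosody:
        # thermometer length code: monosyllabic = 01, disyllabic = 11
        vec[LENGTH_OFFSET + 1] = 1
        if lexeme.n_syllables == 2:
            vec[LENGTH_OFFSET] = 1
        vec[STRESS_OFFSET + lexeme.stress - 1] = 1
    if language_unit == "own":
        language_unit = lexeme.language
    if language_unit is not None:
        if language_unit not in ("A", "B"):
            raise LexiconError(f"language_unit must be 'A', 'B', 'own' or None")
        vec[LANGUAGE_OFFSET + ("A", "B").index(language_unit)] = 1
    return vec


def occupied_slots(lexeme: Lexeme) -> list[int]:
    """0-based indices of template slots occupied by the lexeme's phonemes,
    in phoneme order."""
    slots = align_to_template(lexeme.syllables)
    return [s for s, ph in enumerate(slots) if ph is not None]


def binarize_embedding(real_vector: Sequence[float], threshold: float = -0.175) -> np.ndarray:
    """Binarize a 300-d real-valued embedding: bit i = 1 iff value < threshold."""
    arr = np.asarray(real_vector, dtype=float)
    if arr.ndim != 1 or arr.size != SEM_BITS:
        raise LexiconError(f"embedding must have {SEM_BITS} entries, got shape {arr.shape}")
    return (arr < threshold).astype(np.uint8)


@dataclass
class BilingualLexicon:
    """A set of translation pairs with derived phonological and semantic vectors."""

    lexemes: list[Lexeme]
    sem: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        by_pair: dict[int, set[str]] = {}
        for lx in self.lexemes:
            if lx.key in seen:
                raise LexiconError(f"duplicate (language, orthography): {lx.key}")
            seen.add(lx.key)
            by_pair.setdefault(lx.pair_id, set()).add(lx.language)
        for pid, langs in by_pair.items():
            if langs != {"A", "B"}:
                raise LexiconError(
                    f"pair_id {pid} must have exactly one lexeme per language, got {sorted(langs)}"
                )
        for pid in by_pair:
            if pid in self.sem and self.sem[pid].size != SEM_BITS:
                raise LexiconError(f"semantics for pair {pid} must have {SEM_BITS} bits")
        for lang in ("A", "B"):
            forms = [tuple(encode_phonology(lx, use_prosody=True, language_unit=None))
                     for lx in self.words(lang)]
            if len(set(forms)) != len(forms):
                raise LexiconError(f"phonological vectors not distinct within language {lang}")

    def words(self, language: str) -> list[Lexeme]:
        """Lexemes of one language, in lexicon order."""
        return [lx for lx in self.lexemes if lx.language == language]

    @property
    def n_pairs(self) -> int:
        return len({lx.pair_id for lx in self.lexemes})

    @property
    def counts(self) -> dict[str, int]:
        return {lang: len(self.words(lang)) for lang in ("A", "B")}

    # -- derived vectors ---------------------------------------------------

    def phon_vector(self, lexeme: Lexeme, use_prosody: bool = True,
                    language_unit: str | None = "own") -> np.ndarray:
        return encode_phonology(lexeme, use_prosody, language_unit)

    def sem_vector(self, lexeme_or_pair: Lexeme | int) -> np.ndarray:
        pid = lexeme_or_pair.pair_id if isinstance(lexeme_or_pair, Lexeme) else lexeme_or_pair
        return self.sem[pid]

    def phon_matrix(self, language: str, use_prosody: bool = True,
                    language_unit: str | None = "own") -> np.ndarray:
        """(n_words, 292) matrix over one language's words in lexicon order."""
        return np.stack([encode_phonology(lx, use_prosody, language_unit)
                         for lx in self.words(language)])

    def sem_matrix(self, language: str) -> np.ndarray:
        """(n_words, 300) matrix over one language's words in lexicon order."""
        return np.stack([self.sem[lx.pair_id] for lx in self.words(language)])


# -- synthetic lexicon generation -----------------------------------------

_CONSONANTS = sorted(s for s in _FEATURE_TABLE if not is_vowel(s))
_VOWELS = sorted(s for s in _FEATURE_TABLE if is_vowel(s))

_ORTH = {
    "{": "ae", "@": "uh", "3": "er", "A": "aa", "O": "oo", "E": "eh",
    "I": "ih", "U": "uu", "S": "sh", "Z": "zh", "T": "th", "D": "dh",
    "N": "ng", "tS": "ch", "dZ": "dg", "kh": "kh",
}


def _orthography(sampa: Iterable[str]) -> str:
    return "".join(_ORTH.get(ph, ph) for ph in sampa)


def _sample_syllable(rng: np.random.Generator, max_onset: int, max_coda: int
                     ) -> tuple[str, ...]:
    n_on = rng.choice([0, 1, 2, 3], p=[0.15, 0.55, 0.25, 0.05])
    n_on = min(int(n_on), max_onset)
    n_nuc = int(rng.choice([1, 2], p=[0.85, 0.15]))
    n_coda = rng.choice([0, 1, 2], p=[0.40, 0.45, 0.15])
    n_coda = min(int(n_coda), max_coda)
    phones = [*rng.choice(_CONSONANTS, n_on), *rng.choice(_VOWELS, n_nuc),
              *rng.choice(_CONSONANTS, n_coda)]
    return tuple(str(p) for p in phones)


def _sample_word(rng: np.random.Generator, disyllabic: bool) -> tuple[tuple[str, ...], ...]:
    syl1 = _sample_syllable(rng, max_onset=3, max_coda=2 if disyllabic else 3)
    if not disyllabic:
        return (syl1,)
    _, _, coda1 = _split_syllable(syl1, 1)
    syl2 = _sample_syllable(rng, max_onset=3 - len(coda1), max_coda=3)
    return (syl1, syl2)


def generate_synthetic_lexicon(
    n_pairs: int = 121,
    disyllabic_counts: Mapping[str, int] | None = None,
    sem_ones_target: float = 52.7,
    n_sem_clusters: int = 8,
    sem_flip: float = 0.3,
    seed: int = 0,
) -> BilingualLexicon:
    """Generate a reproducible synthetic bilingual lexicon.

    Emulates the structure of the study vocabulary: ``n_pairs`` translation
    pairs (default 121) with a mono/disyllabic mix (default 39 disyllabic
    language-A and 45 language-B words), sparse binary semantics with an
    expected popcount of ``sem_ones_target`` and cluster structure
    (``n_sem_clusters`` prototypes, each member a lightly perturbed copy),
    identical semantics within a translation pair, and pairwise-distinct
    phonological forms within each language.

    Per-bit flips around a cluster prototype are asymmetric (1->0 with
    probability ``sem_flip``, 0->1 with probability ``sem_flip * p/(1-p)``)
    so that the expected popcount stays at the target.
    """
    if n_pairs < 4:
        raise LexiconError("n_pairs must be at least 4")
    counts = dict(disyllabic_counts or {"A": 39, "B": 45})
    for lang, c in counts.items():
        if c > n_pairs:
            raise LexiconError(f"disyllabic count for {lang} exceeds n_pairs={n_pairs}")
    rng = np.random.default_rng(seed)

    lexemes: list[Lexeme] = []
    for lang in ("A", "B"):
        n_di = counts[lang]
        disyllabic_flags = np.zeros(n_pairs, dtype=bool)
        disyllabic_flags[rng.choice(n_pairs, size=n_di, replace=False)] = True
        forms_seen: set[tuple] = set()
        orth_seen: set[str] = set()
        for pid in range(n_pairs):
            for attempt in range(200):
                syllables = _sample_word(rng, bool(disyllabic_flags[pid]))
                if sum(len(s) for s in syllables) < 2:
                    continue  # words must be splittable into initial/final phones
                try:
                    slots = tuple(align_to_template(syllables))
                except AlignmentError:
                    continue
                if slots in forms_seen:
                    continue
                forms_seen.add(slots)
                break
            else:
                raise LexiconError(
                    f"could not generate {n_pairs} distinct forms for language {lang}"
                )
            stress = 1 if len(syllables) == 1 else int(rng.choice([1, 2], p=[0.75, 0.25]))
            orth = _orthography(ph for syl in syllables for ph in syl)
            if orth in orth_seen:
                orth = f"{orth}{pid}"
            orth_seen.add(orth)
            lexemes.append(Lexeme(orth, lang, syllables, stress, pid))

    p = sem_ones_target / SEM_BITS
    prototypes = (rng.random((n_sem_clusters, SEM_BITS)) < p).astype(np.uint8)
    cluster_of = rng.integers(0, n_sem_clusters, size=n_pairs)
    sem: dict[int, np.ndarray] = {}
    flip_up = sem_flip * p / (1.0 - p)
    for pid in range(n_pairs):
        proto = prototypes[cluster_of[pid]]
        u = rng.random(SEM_BITS)
        flip = np.where(proto == 1, u < sem_flip, u < flip_up)
        sem[pid] = np.where(flip, 1 - proto, proto).astype(np.uint8)

    return BilingualLexicon(lexemes=lexemes, sem=sem)


# -- TSV round trip --------------------------------------------------------

_COLUMNS = ["orthography", "language", "sampa", "stress", "pair_id"]


def save_lexicon(lexicon: BilingualLexicon, path: str | Path) -> None:
    """Write a lexicon as UTF-8 TSV.  The ``sampa`` column space-separates
    phonemes and marks the syllable boundary with ``.``; semantics rows
    follow as ``#sem`` lines (pair_id then the 300 bits)."""
    path = Path(path)
    lines = ["\t".join(_COLUMNS)]
    for lx in lexicon.lexemes:
        sampa = " . ".join(" ".join(syl) for syl in lx.syllables)
        lines.append("\t".join([lx.orthography, lx.language, sampa,
                                str(lx.stress), str(lx.pair_id)]))
    for pid in sorted(lexicon.sem):
        bits = "".join(str(int(b)) for b in lexicon.sem[pid])
        lines.append(f"#sem\t{pid}\t{bits}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_vectors(lexicon: BilingualLexicon, path: str | Path,
                   kind: str = "phon", **encode_kwargs) -> None:
    """Write derived vectors as a TSV matrix: one row per lexeme, first
    column the lexeme key, then the bits.  ``kind`` is "phon" or "sem"."""
    path = Path(path)
    lines = []
    for lx in lexicon.lexemes:
        if kind == "phon":
            vec = encode_phonology(lx, **encode_kwargs)
        elif kind == "sem":
            vec = lexicon.sem[lx.pair_id]
        else:
            raise LexiconError(f"kind must be 'phon' or 'sem', got {kind!r}")
        lines.append("\t".join([lx.key, *map(str, map(int, vec))]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def apply_real_embeddings(lexicon: BilingualLexicon, path: str | Path,
                          threshold: float = -0.175) -> BilingualLexicon:
    """Replace the lexicon's semantics with binarized real-valued embeddings.

    ``path`` is a TSV of one row per translation pair: pair_id then 300
    real values (e.g. exported from a word-embedding model).  Each row is
    binarized with :func:`binarize_embedding` and assigned to both members
    of the pair.  Pairs missing from the file are rejected.
    """
    path = Path(path)
    sem: dict[int, np.ndarray] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        try:
            sem[int(parts[0])] = binarize_embedding([float(x) for x in parts[1:]],
                                                    threshold)
        except (ValueError, LexiconError) as exc:
            raise LexiconError(f"{path}:{lineno}: {exc}") from exc
    missing = {lx.pair_id for lx in lexicon.lexemes} - set(sem)
    if missing:
        raise LexiconError(f"embedding file lacks pairs: {sorted(missing)[:5]}")
    return BilingualLexicon(lexemes=list(lexicon.lexemes), sem=sem)


def load_lexicon(path: str | Path) -> BilingualLexicon:
    """Load a lexicon written by :func:`save_lexicon`.

    Malformed rows are rejected with their line number; lexicon-level
    invariants (pair completeness, distinct forms) are enforced on load.
    """
    path = Path(path)
    lexemes: list[Lexeme] = []
    sem: dict[int, np.ndarray] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t") != _COLUMNS:
        raise LexiconError(f"{path}: missing or malformed header row")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "#sem":
            if len(parts) != 3 or len(parts[2]) != SEM_BITS or set(parts[2]) - {"0", "1"}:
                raise LexiconError(f"{path}:{lineno}: malformed semantics row")
            sem[int(parts[1])] = np.array([int(c) for c in parts[2]], dtype=np.uint8)
            continue
        if len(parts) != len(_COLUMNS):
            raise LexiconError(f"{path}:{lineno}: expected {len(_COLUMNS)} columns")
        orth, lang, sampa, stress, pair_id = parts
        syllables = tuple(
            tuple(tok for tok in syl.split() if tok)
            for syl in sampa.split(".")
        )
        try:
            lexemes.append(Lexeme(orth, lang, syllables, int(stress), int(pair_id)))
        except (LexiconError, ValueError) as exc:
            raise LexiconError(f"{path}:{lineno}: {exc}") from exc
    return BilingualLexicon(lexemes=lexemes, sem=sem)
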
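"""Data model for labeled piano improvisations and score-geometry helpers.

An improvisation is a short (at most 20 s) free piano performance elicited by
a stimulus word.  Words live in a 2x2 design: valence (positive/negative)
crossed with semantic category (morality/logic).  All times are seconds,
pitches are integer MIDI note numbers, and every note occupies the half-open
interval [onset, offset) -- a pitch is *sounding* at time t iff
onset <= t < offset, which makes frame membership unambiguous.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

VALENCES = ("positive", "negative")
CATEGORIES = ("morality", "logic")

#: onsets closer than this are treated as one chord (simultaneity threshold)
DEFAULT_CLUSTER_THRESHOLD = 0.030


class CorpusError(ValueError):
    """Invalid improvisation, corpus or word-set content."""


@dataclass(frozen=True)
class NoteEvent:
    """One keyboard note: [onset, offset) in seconds, MIDI pitch and velocity."""

    onset: float
    offset: float
    pitch: int
    velocity: int

    def __post_init__(self) -> None:
        if not self.offset > self.onset >= 0.0:
            raise CorpusError(
                f"need offset > onset >= 0, got [{self.onset}, {self.offset})"
            )
        if not 0 <= int(self.pitch) <= 127:
            raise CorpusError(f"pitch {self.pitch} outside MIDI range 0-127")
        if not 1 <= int(self.velocity) <= 127:
            raise CorpusError(f"velocity {self.velocity} outside MIDI range 1-127")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def pitch_class(self) -> int:
        return self.pitch % 12


@dataclass(frozen=True)
class Improvisation:
    """A labeled note list for one pianist x word pair."""

    pianist_id: str
    word: str
    valence: str
    category: str
    notes: tuple[NoteEvent, ...]
    max_length: float = 20.0

    def __post_init__(self) -> None:
        if not self.notes:
            raise CorpusError("improvisation has no notes")
        if self.valence not in VALENCES:
            raise CorpusError(f"unknown valence {self.valence!r}")
        if self.category not in CATEGORIES:
            raise CorpusError(f"unknown category {self.category!r}")
        onsets = [n.onset for n in self.notes]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise CorpusError("notes must be sorted by onset")
        if self.span > self.max_length + 1e-9:
            raise CorpusError(
                f"span {self.span:.3f} s exceeds max length {self.max_length} s"
            )

    @property
    def span(self) -> float:
        """Last offset minus first onset, seconds."""
        return max(n.offset for n in self.notes) - self.notes[0].onset


@dataclass(frozen=True)
class WordEntry:
    word_en: str
    word_es: str
    valence: str
    category: str


@dataclass(frozen=True)
class WordSet:
    """The 32 stimulus words: 8 per (valence x category) cell."""

    entries: tuple[WordEntry, ...]

    def __post_init__(self) -> None:
        counts: dict[tuple[str, str], int] = {}
        for e in self.entries:
            counts[(e.valence, e.category)] = counts.get((e.valence, e.category), 0) + 1
        expected = {(v, c) for v in VALENCES for c in CATEGORIES}
        if set(counts) != expected or any(n != 8 for n in counts.values()):
            raise CorpusError(f"word set must have 8 words per cell, got {counts}")
        if len({e.word_en for e in self.entries}) != len(self.entries):
            raise CorpusError("duplicate words in word set")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def lookup(self, word_en: str) -> WordEntry:
        for e in self.entries:
            if e.word_en == word_en:
                return e
        raise KeyError(word_en)

    def words_in_cell(self, valence: str, category: str) -> list[str]:
        return [
            e.word_en
            for e in self.entries
            if e.valence == valence and e.category == category
        ]


def default_word_set() -> WordSet:
    """The packaged 32-word stimulus set (English and Spanish forms)."""
    raw = json.loads(
        resources.files("melosem").joinpath("data/word_set.json").read_text("utf-8")
    )
    return WordSet(tuple(WordEntry(**entry) for entry in raw))


@dataclass(frozen=True)
class Corpus:
    improvisations: tuple[Improvisation, ...]
    word_set: WordSet = field(default_factory=default_word_set)

    def __post_init__(self) -> None:
        known = {e.word_en for e in self.word_set}
        pairs = set()
        for imp in self.improvisations:
            if imp.word not in known:
                raise CorpusError(f"word {imp.word!r} not in word set")
            key = (imp.pianist_id, imp.word)
            if key in pairs:
                raise CorpusError(f"duplicate (pianist, word) pair {key}")
            pairs.add(key)

    def __len__(self) -> int:
        return len(self.improvisations)

    @property
    def pianists(self) -> list[str]:
        seen: dict[str, None] = {}
        for imp in self.improvisations:
            seen.setdefault(imp.pianist_id)
        return list(seen)


# ---------------------------------------------------------------------------
# score geometry
# ---------------------------------------------------------------------------


def sounding_frames(
    notes: Sequence[NoteEvent], step: float
) -> list[tuple[float, frozenset[int]]]:
    """Sample the sounding pitch set on a regular time grid.

    Frames lie at ``t0 + k*step`` for ``k = 0 .. floor((t_end - t0)/step)``
    where ``t0`` is the first onset and ``t_end`` the last offset.  A pitch is
    sounding at ``t`` iff ``onset <= t < offset``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if not notes:
        return []
    t0 = min(n.onset for n in notes)
    t_end = max(n.offset for n in notes)
    n_frames = int((t_end - t0) / step + 1e-9) + 1
    frames = []
    for k in range(n_frames):
        t = t0 + k * step
        frames.append(
            (t, frozenset(n.pitch for n in notes if n.onset <= t < n.offset))
        )
    return frames


def onset_clusters(
    notes: Sequence[NoteEvent], threshold: float = DEFAULT_CLUSTER_THRESHOLD
) -> list[list[NoteEvent]]:
    """Group notes whose onsets fall within ``threshold`` of the cluster start.

    Chords played by hand are never perfectly simultaneous; anything within
    30 ms (default) of the first note of a cluster counts as the same attack.
    """
    ordered = sorted(notes, key=lambda n: n.onset)
    clusters: list[list[NoteEvent]] = []
    for note in ordered:
        if clusters and note.onset - clusters[-1][0].onset <= threshold:
            clusters[-1].append(note)
        else:
            clusters.append([note])
    return clusters


def skyline(
    notes: Sequence[NoteEvent], threshold: float = DEFAULT_CLUSTER_THRESHOLD
) -> list[int]:
    """Melody proxy: the highest pitch of each onset cluster, in time order."""
    if not notes:
        raise CorpusError("skyline of empty note list")
    return [max(n.pitch for n in cluster) for cluster in onset_clusters(notes, threshold)]


# ---------------------------------------------------------------------------
# corpus manifest I/O
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["file", "pianist_id", "word", "valence", "category"]


def save_corpus(corpus: Corpus, directory: str | Path) -> Path:
    """Export a corpus as SMF files plus a ``manifest.csv``; returns the manifest path."""
    from .smf import write_smf  # local import: smf depends on this module

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for imp in corpus.improvisations:
            fname = f"{imp.pianist_id}_{imp.word}.mid"
            write_smf(imp, directory / fname)
            writer.writerow([fname, imp.pianist_id, imp.word, imp.valence, imp.category])
    return manifest


def load_corpus(manifest_path: str | Path, word_set: WordSet | None = None) -> Corpus:
    """Read a manifest CSV and the SMF files it references."""
    from .smf import read_smf

    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    word_set = word_set or default_word_set()
    improvisations = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CorpusError(f"manifest missing columns {sorted(missing)}")
        for row in reader:
            notes = read_smf(directory / row["file"])
            improvisations.append(
                Improvisation(
                    pianist_id=row["pianist_id"],
                    word=row["word"],
                    valence=row["valence"],
                    category=row["category"],
                    notes=tuple(notes),
                )
            )
    return Corpus(tuple(improvisations), word_set)
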
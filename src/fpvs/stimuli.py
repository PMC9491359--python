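"""Morpheme inventories, pseudoword combination, and periodic oddball sequences.

The frequency-tagging oddball paradigm presents base stimuli at a fast fixed
rate (6 Hz here) with a deviant ("oddball") stimulus inserted every nth item
(every 5th, i.e. 1.2 Hz). The stimuli are 7-letter pseudowords built by
concatenating a 4-letter left constituent (a real English stem such as *soft*,
or a matched nonstem such as *terp*) with a 3-letter right constituent (a real
suffix such as *ity*, or a matched nonsuffix such as *ert*). Which constituent
distinguishes oddballs from base items determines what linguistic unit an
oddball-frequency brain response indexes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Morpheme",
    "MorphemeInventory",
    "Pseudoword",
    "ConditionSpec",
    "StimulusSequence",
    "CONDITIONS",
    "STIM_TYPES",
    "InvalidInventoryError",
    "CollisionError",
    "GenerationError",
    "build_combinations",
    "generate_sequence",
    "contrast_envelope",
    "verify_min_distance",
    "load_default_inventory",
    "load_condition0_pools",
    "read_inventory",
]

LEFT_ROLES = ("stem", "nonstem")
RIGHT_ROLES = ("suffix", "nonsuffix")
ROLES = LEFT_ROLES + RIGHT_ROLES

#: stimulus class -> (left role, right role)
STIM_TYPES: Mapping[str, tuple[str, str]] = {
    "stem+suffix": ("stem", "suffix"),
    "nonstem+suffix": ("nonstem", "suffix"),
    "stem+nonsuffix": ("stem", "nonsuffix"),
    "nonstem+nonsuffix": ("nonstem", "nonsuffix"),
}

_ROLE_LENGTH = {"stem": 4, "nonstem": 4, "suffix": 3, "nonsuffix": 3}


class InvalidInventoryError(ValueError):
    """The morpheme inventory violates a structural constraint."""


class CollisionError(ValueError):
    """Two distinct combinations render to the same text."""


class GenerationError(RuntimeError):
    """Sequence generation could not satisfy a constraint within the retry cap."""


@dataclass(frozen=True)
class Morpheme:
    """A single building block: a stem, nonstem, suffix, or nonsuffix."""

    text: str
    role: str
    subset: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidInventoryError(f"unknown role {self.role!r}")
        if not (self.text.isalpha() and self.text == self.text.lower()):
            raise InvalidInventoryError(
                f"morpheme text must be lowercase alphabetic, got {self.text!r}"
            )
        if len(self.text) != _ROLE_LENGTH[self.role]:
            raise InvalidInventoryError(
                f"{self.role} must be {_ROLE_LENGTH[self.role]} letters, "
                f"got {self.text!r}"
            )


@dataclass
class MorphemeInventory:
    """A role-balanced, subset-partitioned collection of morphemes.

    Every role carries the same number of items, split into equally sized
    subsets; pseudowords are formed by crossing constituents *within* a subset.
    """

    items: list[Morpheme]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {role: len(self.by_role(role)) for role in ROLES}
        if len(set(counts.values())) != 1:
            raise InvalidInventoryError(f"unequal role counts: {counts}")
        for role in ROLES:
            texts = [m.text for m in self.by_role(role)]
            if len(set(texts)) != len(texts):
                raise InvalidInventoryError(f"duplicate texts within role {role!r}")
            sizes = {
                s: len([m for m in self.by_role(role) if m.subset == s])
                for s in self.subsets
            }
            if len(set(sizes.values())) != 1 or 0 in sizes.values():
                raise InvalidInventoryError(
                    f"role {role!r} not evenly partitioned across subsets: {sizes}"
                )

    @property
    def subsets(self) -> list[str]:
        return sorted({m.subset for m in self.items})

    @property
    def subset_size(self) -> int:
        role = ROLES[0]
        return len([m for m in self.by_role(role) if m.subset == self.subsets[0]])

    def by_role(self, role: str, subset: str | None = None) -> list[Morpheme]:
        out = [m for m in self.items if m.role == role]
        if subset is not None:
            out = [m for m in out if m.subset == subset]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.text, m.role, m.subset) for m in self.items],
            columns=["text", "role", "subset"],
        )


def read_inventory(path) -> MorphemeInventory:
    """Read an inventory from delimited text with columns text, role, subset."""
    df = pd.read_csv(path, sep="\t")
    missing = {"text", "role", "subset"} - set(df.columns)
    if missing:
        raise InvalidInventoryError(f"inventory file missing columns {missing}")
    return MorphemeInventory(
        [Morpheme(r.text, r.role, str(r.subset)) for r in df.itertuples()]
    )


def load_default_inventory(group: str = "adult") -> MorphemeInventory:
    """Load the bundled morpheme inventory.

    ``group='adult'`` returns the full 12-item-per-role inventory (two subsets
    of 6). ``group='child'`` returns the reduced 6-item-per-role inventory
    (two subsets of 3) drawn from the first six adult items per role.
    """
    ref = resources.files("fpvs.data") / "morpheme_inventory.tsv"
    with resources.as_file(ref) as path:
        inv = read_inventory(path)
    if group == "adult":
        return inv
    if group == "child":
        items = []
        for role in ROLES:
            picked = inv.by_role(role)[:6]
            for i, m in enumerate(picked):
                items.append(Morpheme(m.text, m.role, "A" if i < 3 else "B"))
        return MorphemeInventory(items)
    raise ValueError(f"group must be 'adult' or 'child', got {group!r}")


def load_condition0_pools(group: str = "adult") -> tuple[list[str], list[str]]:
    """Return (word pool, consonant-string pool) for the manipulation check.

    These are synthetic stand-in lists shipped with the package (72 familiar
    4-letter words ending in a consonant, and 72 unpronounceable 4-consonant
    strings); the child variant uses the first 18 of each.
    """
    pools = []
    for name in (
        "condition0_words_synthetic.txt",
        "condition0_consonant_strings_synthetic.txt",
    ):
        ref = resources.files("fpvs.data") / name
        lines = ref.read_text().splitlines()
        pools.append([ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")])
    words, strings = pools
    if group == "child":
        return words[:18], strings[:18]
    return words, strings


@dataclass(frozen=True)
class Pseudoword:
    """A 7-letter pseudoword: left (4-letter) + right (3-letter) constituent."""

    left: Morpheme
    right: Morpheme
    stim_type: str

    def __post_init__(self) -> None:
        if self.stim_type not in STIM_TYPES:
            raise ValueError(f"unknown stimulus type {self.stim_type!r}")
        lrole, rrole = STIM_TYPES[self.stim_type]
        if self.left.role != lrole or self.right.role != rrole:
            raise ValueError(
                f"{self.stim_type} requires roles {lrole}+{rrole}, got "
                f"{self.left.role}+{self.right.role}"
            )
        if self.left.subset != self.right.subset:
            raise ValueError("constituents must come from the same subset")

    @property
    def text(self) -> str:
        return self.left.text + self.right.text


@dataclass(frozen=True)
class ConditionSpec:
    """One oddball/base contrast of the paradigm.

    The oddball and base stimulus classes differ in exactly the constituent
    whose identification the condition probes. Condition 0 is the
    manipulation check: familiar words embedded in consonant strings.
    """

    id: int
    oddball_type: str
    base_type: str

    def __post_init__(self) -> None:
        if not 0 <= self.id <= 4:
            raise ValueError("condition id must be in 0..4")
        if self.oddball_type == self.base_type:
            raise ValueError("oddball and base stimulus classes must differ")
        if self.id == 0 and self.oddball_type != "word":
            raise ValueError("condition 0 uses word oddballs in consonant strings")


#: the five conditions of the paradigm
CONDITIONS: Mapping[int, ConditionSpec] = {
    0: ConditionSpec(0, "word", "consonant_string"),
    1: ConditionSpec(1, "stem+suffix", "nonstem+suffix"),
    2: ConditionSpec(2, "stem+nonsuffix", "nonstem+nonsuffix"),
    3: ConditionSpec(3, "stem+suffix", "stem+nonsuffix"),
    4: ConditionSpec(4, "nonstem+suffix", "nonstem+nonsuffix"),
}


def build_combinations(
    inventory: MorphemeInventory, stim_types: Iterable[str] | None = None
) -> dict[str, list[Pseudoword]]:
    """Cross constituents within each subset to form all pseudowords per type.

    For subset size ``s`` and two subsets, each stimulus type yields ``2 * s**2``
    unique pseudowords (the adult inventory: 2 * 6**2 = 72 per type, 288 total).
    Output order is deterministic given inventory order.
    """
    if stim_types is None:
        stim_types = list(STIM_TYPES)
    out: dict[str, list[Pseudoword]] = {}
    for st in stim_types:
        if st not in STIM_TYPES:
            raise ValueError(f"unknown stimulus type {st!r}")
        lrole, rrole = STIM_TYPES[st]
        combos = [
            Pseudoword(left, right, st)
            for subset in inventory.subsets
            for left in inventory.by_role(lrole, subset)
            for right in inventory.by_role(rrole, subset)
        ]
        texts = [p.text for p in combos]
        if len(set(texts)) != len(texts):
            dup = next(t for t in texts if texts.count(t) > 1)
            raise CollisionError(f"rendered text {dup!r} produced more than once")
        out[st] = combos
    all_texts = [p.text for combos in out.values() for p in combos]
    if len(set(all_texts)) != len(all_texts):
        dup = next(t for t in all_texts if all_texts.count(t) > 1)
        raise CollisionError(f"rendered text {dup!r} collides across types")
    return out


@dataclass
class StimulusSequence:
    """A periodic stimulation stream with oddballs every ``oddball_period`` items.

    ``oddball_positions`` are 1-based: the stream opens with base items and the
    oddball occupies every ``oddball_period``-th slot (5, 10, ..., 360 in the
    reference 60-s, 6-Hz design).
    """

    tokens: list[str]
    base_rate: float
    oddball_period: int
    duration: float
    oddball_positions: frozenset[int] = field(default=frozenset())

    def __post_init__(self) -> None:
        n = len(self.tokens)
        expected = int(round(self.base_rate * self.duration))
        if n != expected:
            raise ValueError(f"token count {n} != base_rate*duration = {expected}")
        want = frozenset(range(self.oddball_period, n + 1, self.oddball_period))
        if self.oddball_positions != want:
            raise ValueError("oddball positions must be every period-th 1-based index")

    @property
    def n_oddballs(self) -> int:
        return len(self.oddball_positions)

    @property
    def onsets(self) -> np.ndarray:
        """Stimulus onset times in seconds (item i starts at (i-1)/base_rate)."""
        return np.arange(len(self.tokens)) / self.base_rate

    def is_oddball(self) -> np.ndarray:
        mask = np.zeros(len(self.tokens), dtype=bool)
        mask[[p - 1 for p in self.oddball_positions]] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(1, len(self.tokens) + 1),
                "token": self.tokens,
                "is_oddball": self.is_oddball(),
                "onset_s": self.onsets,
            }
        )

    def write(self, path, config: dict | None = None) -> None:
        """Write the sequence as TSV plus a JSON sidecar echoing the config."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = {
            "base_rate_hz": self.base_rate,
            "oddball_period": self.oddball_period,
            "duration_s": self.duration,
            "n_tokens": len(self.tokens),
            "n_oddballs": self.n_oddballs,
        }
        if config:
            sidecar["config"] = config
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def verify_min_distance(tokens: Sequence[str], min_distance: int) -> bool:
    """Exhaustive pairwise check: no identical texts at index distance < min_distance."""
    n = len(tokens)
    for i in range(n):
        for j in range(i + 1, min(i + min_distance, n)):
            if tokens[i] == tokens[j]:
                return False
    return True


def _texts(pool: Sequence) -> list[str]:
    return [p if isinstance(p, str) else p.text for p in pool]


def generate_sequence(
    cond: ConditionSpec,
    oddball_pool: Sequence,
    base_pool: Sequence,
    duration: float = 60.0,
    base_rate: float = 6.0,
    oddball_period: int = 5,
    repetition_policy: str = "unique",
    seed: int | None = None,
    max_retries: int = 100,
) -> StimulusSequence:
    """Generate one constraint-satisfying stimulation sequence.

    Oddballs occupy every ``oddball_period``-th (1-based) slot. Under the
    ``unique`` policy each oddball slot receives a distinct pool item (the
    adult design: 72 unique oddballs); under ``k_repeats`` the pool is tiled
    so every item appears exactly ``slots / len(pool)`` times (the child
    design: 18 items x 4). Base slots are filled uniformly with replacement.
    No identical text may recur at index distance < ``oddball_period``;
    rejection sampling with a retry cap enforces this.
    """
    odd_texts = _texts(oddball_pool)
    base_texts = _texts(base_pool)
    if not odd_texts or not base_texts:
        raise ValueError("stimulus pools must be non-empty")
    n_tokens = int(round(base_rate * duration))
    positions = list(range(oddball_period, n_tokens + 1, oddball_period))
    n_slots = len(positions)

    rng = np.random.default_rng(seed)
    if repetition_policy == "unique":
        if len(odd_texts) < n_slots:
            raise GenerationError(
                f"unique policy needs >= {n_slots} oddballs, pool has {len(odd_texts)}"
            )
        oddballs = list(rng.permutation(odd_texts)[:n_slots])
    elif repetition_policy == "k_repeats":
        if n_slots % len(odd_texts):
            raise GenerationError(
                f"k_repeats policy needs pool size dividing {n_slots} slots, "
                f"got {len(odd_texts)}"
            )
        k = n_slots // len(odd_texts)
        oddballs = list(rng.permutation(odd_texts * k))
    else:
        raise ValueError(f"unknown repetition policy {repetition_policy!r}")

    for _ in range(max_retries):
        tokens: list[str | None] = [None] * n_tokens
        for pos, text in zip(positions, oddballs):
            tokens[pos - 1] = text
        ok = True
        for i in range(n_tokens):
            if tokens[i] is not None:
                continue
            # forbid any text already placed within the min-distance window
            lo, hi = max(0, i - oddball_period + 1), min(n_tokens, i + oddball_period)
            banned = {tokens[j] for j in range(lo, hi) if tokens[j] is not None}
            candidates = [t for t in base_texts if t not in banned]
            if not candidates:
                ok = False
                break
            tokens[i] = candidates[rng.integers(len(candidates))]
        if ok and verify_min_distance(tokens, oddball_period):  # type: ignore[arg-type]
            return StimulusSequence(
                tokens=list(tokens),  # type: ignore[arg-type]
                base_rate=base_rate,
                oddball_period=oddball_period,
                duration=duration,
                oddball_positions=frozenset(positions),
            )
        oddballs = list(rng.permutation(oddballs))
    raise GenerationError(
        "could not satisfy the min-repetition-distance constraint "
        f"(distance >= {oddball_period}) within {max_retries} retries"
    )


def contrast_envelope(t, cycle_duration: float):
    """Sinusoidal contrast modulation within one presentation cycle.

    contrast(t) = (1 - cos(2*pi*t / T)) / 2 for 0 <= t <= T: zero at cycle
    onset and offset, full contrast at the half cycle (83.5 ms into the 167-ms
    cycle of the 6-Hz design). Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > cycle_duration):
        raise ValueError(f"t must lie within [0, {cycle_duration}]")
    out = (1.0 - np.cos(2.0 * np.pi * t / cycle_duration)) / 2.0
    return out if out.shape else float(out)
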
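"""Task design: color-oddity displays and inter-trial condition structure.

The task presents four items at the corners of an imaginary square: one
odd-colored target among three homogeneously colored distractors.  Colors are
drawn from a fixed pool of four.  Each trial (except the first) is classified
by how its target (T) and distractor (D) colors relate to the previous trial's
colors: repeated (R, same color in the same role), swapped (S, the color
reappears in the opposite role) or new (N, the color was absent).  Only seven
of the nine label combinations are geometrically possible; TRDS and TSDR
would require the current target and distractor to share a color.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four-color pool.  RGB triples are display metadata only; the model
#: operates on color identity.
COLOR_POOL: tuple[str, ...] = ("red", "green", "blue", "purple")

COLOR_RGB: dict[str, tuple[int, int, int]] = {
    "red": (195, 107, 107),
    "green": (61, 152, 63),
    "blue": (114, 125, 180),
    "purple": (177, 104, 190),
}

#: The seven possible inter-trial conditions.
CONDITIONS: tuple[str, ...] = (
    "TRDR", "TRDN", "TNDR", "TSDN", "TNDS", "TSDS", "TNDN",
)

#: Partial conditions (exactly one color carried over from trial n-1).
PARTIAL_CONDITIONS: tuple[str, ...] = ("TRDN", "TNDR", "TSDN", "TNDS")

#: Corner labels, as (column, row): e.g. "TL" = top-left.
CORNERS: tuple[str, ...] = ("TL", "TR", "BL", "BR")

#: Side of the imaginary square, cm (center-to-center item spacing).
SQUARE_SIDE_CM: float = 13.0

#: Center of the square in workspace coordinates (x, y), cm.  The reach
#: starts at the origin (bottom-center of the workspace) and moves up.
SQUARE_CENTER_CM: tuple[float, float] = (0.0, 20.0)


def corner_position(corner: str) -> tuple[float, float]:
    """Workspace (x, y) position in cm of a corner label."""
    half = SQUARE_SIDE_CM / 2.0
    cx, cy = SQUARE_CENTER_CM
    dx = -half if corner[1] == "L" else half
    dy = half if corner[0] == "T" else -half
    return (cx + dx, cy + dy)


@dataclass(frozen=True)
class Display:
    """One search display: an odd-colored target among three same-colored
    distractors at the corners of the square."""

    target_color: str
    distractor_color: str
    target_corner: str = "BR"

    def __post_init__(self) -> None:
        if self.target_color not in COLOR_POOL:
            raise ValueError(f"unknown color {self.target_color!r}")
        if self.distractor_color not in COLOR_POOL:
            raise ValueError(f"unknown color {self.distractor_color!r}")
        if self.target_color == self.distractor_color:
            raise ValueError("display must contain a unique odd color")
        if self.target_corner not in CORNERS:
            raise ValueError(f"unknown corner {self.target_corner!r}")

    @property
    def distractor_corners(self) -> tuple[str, ...]:
        return tuple(c for c in CORNERS if c != self.target_corner)


def all_color_pairs() -> list[tuple[str, str]]:
    """All 12 valid (target_color, distractor_color) assignments."""
    return [(t, d) for t, d in itertools.permutations(COLOR_POOL, 2)]


def classify_transition(prev: Display, cur: Display) -> str:
    """Label the inter-trial condition of ``cur`` given ``prev``.

    The label is a pure function of color identities; target location plays
    no role (location repetition effects are weak and not modeled).
    """
    if cur.target_color == prev.target_color:
        t = "R"
    elif cur.target_color == prev.distractor_color:
        t = "S"
    else:
        t = "N"
    if cur.distractor_color == prev.distractor_color:
        d = "R"
    elif cur.distractor_color == prev.target_color:
        d = "S"
    else:
        d = "N"
    return f"T{t}D{d}"


@dataclass
class TrialSequence:
    """An ordered experiment's worth of displays plus bookkeeping."""

    trials: list[Display]
    blocks: int
    trials_per_block: int
    seed: int
    conditions: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conditions:
            self.conditions = [None] + [
                classify_transition(a, b)
                for a, b in zip(self.trials, self.trials[1:])
            ]

    def condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for c in self.conditions[1:]:
            counts[c] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (disp, cond) in enumerate(zip(self.trials, self.conditions)):
            rows.append(
                {
                    "trial": i + 1,
                    "block": i // self.trials_per_block + 1,
                    "target_color": disp.target_color,
                    "distractor_color": disp.distractor_color,
                    "target_corner": disp.target_corner,
                    "condition": cond if cond is not None else "NA",
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrialSequence":
        df = pd.read_csv(path)
        trials = [
            Display(r.target_color, r.distractor_color, r.target_corner)
            for r in df.itertuples()
        ]
        blocks = int(df["block"].max())
        return cls(
            trials=trials,
            blocks=blocks,
            trials_per_block=len(trials) // blocks,
            seed=-1,
        )


def generate_sequence(
    blocks: int = 7,
    trials_per_block: int = 120,
    tolerance: int = 5,
    seed: int = 0,
    max_restarts: int = 1000,
) -> TrialSequence:
    """Generate a pseudo-random trial sequence with approximately equal
    condition counts.

    Construction is a quota-constrained Markov walk: the total number of
    transitions is partitioned into per-condition quotas within ``tolerance``
    of the equal share, and each successive display is drawn uniformly from
    the displays whose transition label still has quota.  From any display
    all seven labels remain reachable, so the walk cannot dead-end; restarts
    are retained defensively.

    Raises
    ------
    ValueError
        If the requested tolerance is infeasible (no integer quota partition
        exists) or the preconditions are violated.
    """
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    if trials_per_block < 14:
        raise ValueError("trials_per_block must be >= 14 (two per condition)")
    n_trials = blocks * trials_per_block
    n_trans = n_trials - 1
    base, rem = divmod(n_trans, 7)
    if rem != 0 and tolerance < 1:
        raise ValueError(
            f"cannot balance {n_trans} transitions over 7 conditions "
            f"with tolerance {tolerance}"
        )
    rng = np.random.default_rng(seed)

    pairs = all_color_pairs()
    for _ in range(max_restarts):
        # Quotas: equal share, remainder spread over random conditions.
        quota = {c: base for c in CONDITIONS}
        for c in rng.choice(len(CONDITIONS), size=rem, replace=False):
            quota[CONDITIONS[c]] += 1

        first = Display(
            *pairs[rng.integers(len(pairs))],
            CORNERS[rng.integers(4)],
        )
        trials = [first]
        ok = True
        for _ in range(n_trans):
            prev = trials[-1]
            candidates = [
                (t, d)
                for (t, d) in pairs
                if quota[
                    classify_transition(prev, Display(t, d))
                ] > 0
            ]
            if not candidates:
                ok = False
                break
            t, d = candidates[rng.integers(len(candidates))]
            nxt = Display(t, d, CORNERS[rng.integers(4)])
            quota[classify_transition(prev, nxt)] -= 1
            trials.append(nxt)
        if ok:
            seq = TrialSequence(
                trials=trials,
                blocks=blocks,
                trials_per_block=trials_per_block,
                seed=seed,
            )
            counts = seq.condition_counts()
            share = n_trans / 7.0
            if all(abs(v - share) <= tolerance for v in counts.values()):
                return seq
    raise ValueError("no balanced sequence found within the restart budget")
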
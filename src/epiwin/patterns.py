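"""Sliding-window pattern generation and training-set assembly.

Each residue of an antigen yields exactly one fixed-length window ("pattern")
centered on it; terminal residues are reachable because the sequence is
padded with (W-1)/2 dummy 'X' on both sides.  A pattern is positive iff its
central residue is antibody-interacting.  Training sets come in two regimes:
*balanced* (all positives plus an equal-size random sample of negatives) and
*realistic* (every pattern, natural class imbalance preserved).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .io import AntigenRecord


@dataclass(frozen=True)
class Pattern:
    """A fixed-length window over the 21-letter alphabet (20 aa + 'X').

    ``center_position`` is 1-based in the source antigen; the window's middle
    character is always the source residue there, never 'X'.  ``label`` is
    1 (interacting), 0 (non-interacting) or None for prediction-time windows.
    """

    window: str
    center_position: int
    antigen_id: str
    label: int | None

    @property
    def W(self) -> int:
        return len(self.window)


@dataclass
class PatternSet:
    patterns: list[Pattern]
    regime: Literal["balanced", "realistic"]
    seed: int | None

    def counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        pos = sum(1 for p in self.patterns if p.label == 1)
        return pos, len(self.patterns) - pos


def _check_window(W: int) -> None:
    if W % 2 == 0 or W < 1:
        raise ValueError(f"window length must be odd and >= 1, got {W}")


def pad_sequence(sequence: str, W: int) -> str:
    """Add (W-1)/2 dummy 'X' residues on both sides of the sequence.

    For W=17 that is 8 'X' on each side, so every residue — including the
    termini — has a full window.
    """
    _check_window(W)
    pad = "X" * ((W - 1) // 2)
    return pad + sequence + pad


def generate_patterns(
    antigen: AntigenRecord, W: int, labeled: bool = True
) -> list[Pattern]:
    """One overlapping window per residue, label copied from the center.

    With ``labeled=True`` (training mode) the antigen must carry labels;
    with ``labeled=False`` windows are produced with ``label=None`` so a
    plain sequence suffices at prediction time.
    """
    _check_window(W)
    if labeled and antigen.labels is None:
        raise ValueError(
            f"antigen {antigen.id!r} has no labels; pass labeled=False for "
            "prediction-time patterns"
        )
    padded = pad_sequence(antigen.sequence, W)
    out = []
    for i in range(len(antigen.sequence)):
        window = padded[i : i + W]
        label = antigen.labels[i] if labeled else None
        out.append(
            Pattern(
                window=window,
                center_position=i + 1,
                antigen_id=antigen.id,
                label=label,
            )
        )
    return out


def generate_all_patterns(
    antigens: Iterable[AntigenRecord], W: int, labeled: bool = True
) -> list[Pattern]:
    """Concatenate :func:`generate_patterns` over a collection of antigens."""
    out: list[Pattern] = []
    for antigen in antigens:
        out.extend(generate_patterns(antigen, W, labeled=labeled))
    return out


def assemble_set(
    patterns: Sequence[Pattern],
    regime: Literal["balanced", "realistic"],
    seed: int | None = None,
) -> PatternSet:
    """Assemble a training set in the balanced or realistic regime.

    Balanced keeps every positive and draws an equal-size uniform sample of
    negatives without replacement (seeded, reproducible); realistic keeps
    every pattern unchanged.
    """
    positives = [p for p in patterns if p.label == 1]
    negatives = [p for p in patterns if p.label == 0]
    if any(p.label is None for p in patterns):
        raise ValueError("cannot assemble a training set from unlabeled patterns")
    if not positives:
        raise ValueError("no positive patterns: nothing to balance toward")

    if regime == "realistic":
        return PatternSet(list(patterns), "realistic", seed)
    if regime != "balanced":
        raise ValueError(f"unknown regime {regime!r}")

    if len(negatives) < len(positives):
        raise ValueError(
            f"cannot balance: {len(negatives)} negatives < {len(positives)} positives"
        )
    if seed is None:
        raise ValueError("balanced subsampling requires a seed for reproducibility")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=len(positives), replace=False)
    sampled = [negatives[i] for i in sorted(idx)]
    return PatternSet(positives + sampled, "balanced", seed)


@dataclass
class DedupResult:
    patterns: list[Pattern]
    n_duplicates_removed: int
    n_conflicts: int
    conflict_windows: list[str]


def deduplicate_patterns(patterns: Sequence[Pattern]) -> DedupResult:
    """Collapse exact duplicate window strings; drop label-contradictory ones.

    Identity is the window string alone.  A window string seen with both
    labels is a contradictory training point: all its occurrences are dropped
    and reported.  Otherwise the first occurrence is retained.
    """
    by_window: dict[str, list[Pattern]] = defaultdict(list)
    for p in patterns:
        by_window[p.window].append(p)

    kept: list[Pattern] = []
    conflicts: list[str] = []
    removed = 0
    for p in patterns:
        group = by_window[p.window]
        labels = {q.label for q in group}
        if len(labels) > 1:
            if p is group[0]:
                conflicts.append(p.window)
            removed += 1
            continue
        if p is group[0]:
            kept.append(p)
        else:
            removed += 1
    return DedupResult(kept, removed, len(conflicts), conflicts)


def patterns_to_frame(patterns: Sequence[Pattern]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "antigen_id": [p.antigen_id for p in patterns],
            "center_position": [p.center_position for p in patterns],
            "window": [p.window for p in patterns],
            "label": [p.label for p in patterns],
        }
    )


def write_patterns(patterns: Sequence[Pattern], path: str | Path) -> None:
    patterns_to_frame(patterns).to_csv(path, sep="\t", index=False)
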
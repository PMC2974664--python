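"""The three window encodings: binary (BPP), physico-chemical (PPP) and
composition (CPP) profiles of patterns.

BPP one-hot-encodes every window position over a 21-letter alphabet
(20 amino acids + dummy 'X'), giving a 21·W vector.  PPP replaces each
position by five normalized property values (5·W).  CPP discards order
entirely and reports the percent amino-acid composition of the window:
20 values, comp(i) = 100·R_i/N with N = W window positions (padding 'X'
occupies no bin, so terminal windows sum to less than 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.datasets import dump_svmlight_file

from .patterns import Pattern

#: Fixed alphabet order for BPP one-hot blocks: alphabetical, 'X' last.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
FULL_ALPHABET = ALPHABET + "X"
_INDEX = {aa: i for i, aa in enumerate(FULL_ALPHABET)}
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

Encoding = Literal["bpp", "ppp", "cpp"]

#: Per-position property order emitted by the PPP encoder.
PPP_PROPERTY_ORDER = [
    "parker_hydrophilicity",
    "karplus_schulz_flexibility",
    "grantham_polarity",
    "ponnuswamy_polarity",
    "kolaskar_antigenicity",
]


@dataclass
class PropertyScaleTable:
    """Five physico-chemical scales, min-max normalized to [0,1].

    ``values`` maps each standard residue to its 5-vector in
    :data:`PPP_PROPERTY_ORDER`; the dummy 'X' receives each property's
    column mean so padding positions are neutral.
    """

    values: dict[str, np.ndarray]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyScaleTable":
        df = pd.read_csv(path, sep="\t", comment="#").set_index("residue")
        missing = set(ALPHABET) - set(df.index)
        if missing:
            raise ValueError(f"scale table missing residues: {sorted(missing)}")
        missing_cols = set(PPP_PROPERTY_ORDER) - set(df.columns)
        if missing_cols:
            raise ValueError(f"scale table missing columns: {sorted(missing_cols)}")
        df = df.loc[list(ALPHABET), PPP_PROPERTY_ORDER].astype(float)
        norm = (df - df.min()) / (df.max() - df.min())
        values = {aa: norm.loc[aa].to_numpy() for aa in ALPHABET}
        values["X"] = norm.mean(axis=0).to_numpy()
        return cls(values)

    @classmethod
    def default(cls) -> "PropertyScaleTable":
        with resources.as_file(
            resources.files("epiwin.data") / "property_scales.tsv"
        ) as p:
            return cls.from_tsv(p)


def _check_alphabet(window: str) -> None:
    bad = set(window) - set(FULL_ALPHABET)
    if bad:
        raise ValueError(f"window contains characters outside the alphabet: {sorted(bad)}")


def encode_bpp(pattern: Pattern | str) -> np.ndarray:
    """One-hot encode a window: 21 components per position, 'A' first, 'X' last."""
    window = pattern.window if isinstance(pattern, Pattern) else pattern
    _check_alphabet(window)
    vec = np.zeros(21 * len(window))
    for pos, aa in enumerate(window):
        vec[21 * pos + _INDEX[aa]] = 1.0
    return vec


def encode_ppp(
    pattern: Pattern | str, scales: PropertyScaleTable | None = None
) -> np.ndarray:
    """Encode a window as five normalized property values per position."""
    window = pattern.window if isinstance(pattern, Pattern) else pattern
    _check_alphabet(window)
    if scales is None:
        scales = PropertyScaleTable.default()
    return np.concatenate([scales.values[aa] for aa in window])


def encode_cpp(pattern: Pattern | str) -> np.ndarray:
    """Percent amino-acid composition of the window: comp(i) = 100·R_i/W.

    The denominator counts all W positions including padding 'X', which
    itself occupies no bin — so windows overlapping a terminus sum to < 100,
    an informative signature of terminal location.
    """
    window = pattern.window if isinstance(pattern, Pattern) else pattern
    _check_alphabet(window)
    counts = np.zeros(20)
    for aa in window:
        if aa != "X":
            counts[_AA_INDEX[aa]] += 1.0
    return counts / len(window) * 100.0


def feature_dimension(encoding: Encoding, W: int) -> int:
    """Output dimension as a function of (encoding, W) alone."""
    return {"bpp": 21 * W, "ppp": 5 * W, "cpp": 20}[encoding]


def encode_patterns(
    patterns: Sequence[Pattern],
    encoding: Encoding,
    scales: PropertyScaleTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a homogeneous pattern collection into (X, y) arrays.

    All windows must share one length.  ``y`` entries are -1 for unlabeled
    (prediction-time) patterns.
    """
    if not patterns:
        raise ValueError("no patterns to encode")
    widths = {p.W for p in patterns}
    if len(widths) > 1:
        raise ValueError(f"mixed window lengths in one set: {sorted(widths)}")
    if encoding == "bpp":
        X = np.stack([encode_bpp(p) for p in patterns])
    elif encoding == "ppp":
        scales = scales or PropertyScaleTable.default()
        X = np.stack([encode_ppp(p, scales) for p in patterns])
    elif encoding == "cpp":
        X = np.stack([encode_cpp(p) for p in patterns])
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    y = np.array([-1 if p.label is None else p.label for p in patterns])
    return X, y


def write_svmlight(X: np.ndarray, y: np.ndarray, path: str | Path) -> None:
    """Write an encoded set in SVM-light sparse format for interoperability."""
    dump_svmlight_file(X, y, str(path), zero_based=False)
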
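"""Reading and writing the formats the predictor touches.

Antigens travel as FASTA; per-residue interaction labels travel as a TSV
sidecar (``antigen_id``, 1-based ``position``, ``label`` in {0, 1}); kernel
settings are accepted as SVM-light-style parameter strings such as
``"t 2 g 0.01 j 1 c 1"``.  Positions are 1-based everywhere a file or a
message is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import SVMConfig

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Deterministic substitutions for non-standard letters: ambiguity codes map
#: to their most common resolution, everything else to the dummy 'X'.
SANITIZE_MAP = {"B": "N", "Z": "Q", "U": "C"}


@dataclass
class AntigenRecord:
    """An identified amino-acid sequence with optional per-residue labels.

    ``labels[i] == 1`` marks residue ``i + 1`` (1-based) as
    antibody-interacting.  When labels are present their length must equal
    the sequence length.
    """

    id: str
    sequence: str
    labels: list[int] | None = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = [int(x) for x in self.labels]
            if len(self.labels) != len(self.sequence):
                raise ValueError(
                    f"antigen {self.id!r}: {len(self.labels)} labels for a "
                    f"{len(self.sequence)}-residue sequence"
                )
            bad = set(self.labels) - {0, 1}
            if bad:
                raise ValueError(f"antigen {self.id!r}: labels must be 0/1, got {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


def sanitize_sequence(seq: str, record_id: str = "?") -> str:
    """Uppercase and map non-standard letters onto the 20+X alphabet.

    B→N, Z→Q, U→C; any other non-standard letter (J, O, ...) becomes 'X'.
    Every substitution is logged — never silently dropped.
    """
    out = []
    for i, raw in enumerate(seq):
        ch = raw.upper()
        if ch in STANDARD_AA:
            out.append(ch)
            continue
        sub = SANITIZE_MAP.get(ch, "X")
        logger.warning(
            "antigen %s position %d: non-standard residue %r substituted with %r",
            record_id, i + 1, raw, sub,
        )
        out.append(sub)
    return "".join(out)


def read_fasta(path: str | Path) -> list[AntigenRecord]:
    """Read antigen sequences from a FASTA file, one record per entry.

    Ids are the first whitespace-delimited token of each header; entry order
    is preserved.  Non-standard residues are substituted per
    :func:`sanitize_sequence` with a logged warning.
    """
    records = [
        AntigenRecord(id=rec.id, sequence=sanitize_sequence(str(rec.seq), rec.id))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA entries found in {path}")
    return records


def write_fasta(records: Iterable[AntigenRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_label_sidecar(path: str | Path) -> dict[str, dict[int, int]]:
    """Read a TSV of (antigen_id, position, label) rows.

    Returns a map ``antigen_id -> {position: label}`` with 1-based positions.
    Duplicate (id, position) rows are an error naming the offending row.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"antigen_id": str, "position": int, "label": int},
    )
    required = {"antigen_id", "position", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label sidecar {path} missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["antigen_id", "position"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate label row for antigen {row.antigen_id!r} "
            f"position {int(row.position)}"
        )
    if (df["position"] < 1).any():
        raise ValueError("positions in label sidecar must be >= 1 (1-based)")
    if not df["label"].isin([0, 1]).all():
        raise ValueError("labels in sidecar must be 0 or 1")
    out: dict[str, dict[int, int]] = {}
    for rec_id, grp in df.groupby("antigen_id", sort=False):
        out[str(rec_id)] = dict(zip(grp["position"], grp["label"]))
    return out


def attach_labels(
    records: Sequence[AntigenRecord], sidecar: Mapping[str, Mapping[int, int]]
) -> list[AntigenRecord]:
    """Attach sidecar labels to matching records; positions not listed are 0.

    Sidecar ids with no matching record, or positions beyond the sequence
    length, are errors.
    """
    by_id = {r.id: r for r in records}
    unknown = set(sidecar) - set(by_id)
    if unknown:
        raise ValueError(f"sidecar refers to unknown antigen ids: {sorted(unknown)}")
    out = []
    for rec in records:
        pos_labels = sidecar.get(rec.id)
        if pos_labels is None:
            out.append(rec)
            continue
        labels = [0] * len(rec.sequence)
        for pos, lab in pos_labels.items():
            if not 1 <= pos <= len(rec.sequence):
                raise ValueError(
                    f"antigen {rec.id!r}: label position {pos} outside "
                    f"1..{len(rec.sequence)}"
                )
            labels[pos - 1] = int(lab)
        out.append(AntigenRecord(rec.id, rec.sequence, labels))
    return out


def write_label_sidecar(records: Iterable[AntigenRecord], path: str | Path) -> None:
    """Write every labeled residue of every record as a sidecar row."""
    rows = []
    for rec in records:
        if rec.labels is None:
            raise ValueError(f"antigen {rec.id!r} has no labels to write")
        for pos, lab in enumerate(rec.labels, start=1):
            rows.append((rec.id, pos, lab))
    df = pd.DataFrame(rows, columns=["antigen_id", "position", "label"])
    df.to_csv(path, sep="\t", index=False)


def write_score_table(df: pd.DataFrame, path: str | Path, threshold: float) -> None:
    """Write a per-residue prediction table with a provenance comment line.

    Calls use the inclusive convention: score == threshold is positive.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# per-residue epitope predictions; call_at_threshold uses "
            f"score >= {threshold} (inclusive)\n"
        )
        df.to_csv(fh, sep="\t", index=False)


_KNOWN_FLAGS = {"t", "g", "j", "c", "d"}


def parse_svmlight_params(text: str) -> SVMConfig:
    """Parse an SVM-light-style parameter string into an :class:`SVMConfig`.

    ``t 2 g <gamma>`` selects the RBF kernel, ``t 1 d <degree>`` a polynomial
    kernel; ``c`` is the margin trade-off and ``j`` the cost factor that
    up-weights training errors on positives.  Unknown flags and flags missing
    a value are errors.

    >>> cfg = parse_svmlight_params("t 2 g 0.01 j 1 c 1")
    >>> cfg.kernel, cfg.gamma, cfg.C, cfg.j
    ('rbf', 0.01, 1.0, 1.0)
    """
    tokens = text.split()
    if len(tokens) % 2 != 0:
        raise ValueError(f"parameter string {text!r}: flag without a value")
    params: dict[str, float] = {}
    for flag, value in zip(tokens[::2], tokens[1::2]):
        flag = flag.lstrip("-")
        if flag not in _KNOWN_FLAGS:
            raise ValueError(f"unknown SVM flag {flag!r} in {text!r}")
        try:
            params[flag] = float(value)
        except ValueError as exc:
            raise ValueError(f"flag {flag!r} has non-numeric value {value!r}") from exc

    t = int(params.get("t", 2))
    if t == 2:
        if "g" not in params:
            raise ValueError("RBF kernel (t 2) requires a gamma value (g)")
        return SVMConfig(
            kernel="rbf", gamma=params["g"],
            C=params.get("c", 1.0), j=params.get("j", 1.0),
        )
    if t == 1:
        return SVMConfig(
            kernel="poly", degree=int(params.get("d", 1)), gamma=params.get("g"),
            C=params.get("c", 1.0), j=params.get("j", 1.0),
        )
    raise ValueError(f"unsupported kernel type t={t} (use t 1 or t 2)")
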
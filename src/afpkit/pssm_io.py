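"""Position-specific scoring matrix (PSSM) parsing, normalization, partition.

A PSSM is the L x 20 profile PSI-BLAST writes for a query of length L: one
row per residue, one column per amino-acid type in the fixed PSI-BLAST
column order. Both PSSM descriptors in this toolkit consume a normalized
profile (elementwise logistic sigmoid, mapping log-odds onto (0, 1)) that is
then partitioned by row into three contiguous blocks — "slices" for the
tri-sliced descriptor, "segments" for the segmentation-autocorrelation one.
The first two blocks get floor(L/3) rows each and the remainder goes to the
third.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

#: Fixed PSI-BLAST column ordering of the 20 amino acids.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Number of score columns in a profile.
PSSM_WIDTH = 20

PARTITION_MODES = ("slice", "segment")


class PSSMParseError(ValueError):
    """A PSSM file does not conform to the PSI-BLAST ASCII dialect."""


@dataclass
class PSSMMatrix:
    """An L x 20 evolutionary profile for one sequence.

    ``scores`` holds the first (log-odds) block of the PSI-BLAST ASCII file
    as reals; after :func:`normalize_pssm` every entry lies in (0, 1) and
    ``normalized`` is True. ``residue_column`` is the query-residue echo
    column of the file.
    """

    record_id: str
    scores: np.ndarray
    residue_column: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != PSSM_WIDTH:
            raise ValueError(
                f"PSSM scores must have exactly {PSSM_WIDTH} columns, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residue_column):
            raise ValueError(
                f"PSSM row count {self.scores.shape[0]} does not match "
                f"residue column length {len(self.residue_column)}"
            )
        if self.scores.shape[0] == 0:
            raise ValueError("PSSM must have at least one row")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class PartitionPlan:
    """Three half-open, 0-based row ranges covering all L rows in order."""

    mode: str
    boundaries: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return tuple(stop - start for start, stop in self.boundaries)  # type: ignore[return-value]


def read_pssm_ascii(
    path: str | Path,
    record_id: str | None = None,
    expected_sequence: str | None = None,
) -> PSSMMatrix:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first block of 20 log-odds columns is kept. Data rows carry
    44 whitespace-delimited fields: position, residue, 20 log-odds scores,
    20 weighted percentages and two trailing floats. Header and footer
    lines (those not starting with a position index) are skipped.

    When ``expected_sequence`` is given and disagrees with the file's
    residue echo column, a warning is emitted but the PSSM is retained —
    PSI-BLAST masks low-complexity residues to X in that column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PSSM file not found: {path}")
    rows: list[list[float]] = []
    residues: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens or not tokens[0].isdigit():
            continue  # header, footer or blank line
        if len(tokens) != 44:
            raise PSSMParseError(
                f"{path}, line {lineno}: expected 44 fields "
                f"(position, residue, 20 scores, 20 percentages, 2 stats), "
                f"got {len(tokens)}"
            )
        residue = tokens[1]
        if len(residue) != 1 or not residue.isalpha():
            raise PSSMParseError(
                f"{path}, line {lineno}: expected a single residue letter, got {residue!r}"
            )
        try:
            rows.append([float(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise PSSMParseError(f"{path}, line {lineno}: non-numeric score ({exc})") from exc
        residues.append(residue.upper())
    if not rows:
        raise PSSMParseError(f"{path}: no PSSM rows found")
    residue_column = "".join(residues)
    if expected_sequence is not None and residue_column != expected_sequence.upper():
        warnings.warn(
            f"{path}: residue column disagrees with the paired sequence "
            f"(PSI-BLAST may mask low-complexity residues); PSSM retained",
            stacklevel=2,
        )
    return PSSMMatrix(
        record_id=record_id or path.stem,
        scores=np.array(rows, dtype=float),
        residue_column=residue_column,
        normalized=False,
    )


def normalize_pssm(pssm: PSSMMatrix) -> PSSMMatrix:
    """Squash every log-odds entry through the logistic sigmoid 1/(1+e^-t).

    The map is monotone, so the within-column ordering of scores is
    preserved while the range becomes (0, 1). Re-normalizing an already
    normalized profile would silently compress it towards 0.5 and is an
    error.
    """
    if pssm.normalized:
        raise ValueError(f"PSSM {pssm.record_id!r} is already normalized")
    return replace(pssm, scores=expit(pssm.scores), normalized=True)


def plan_partition(length: int, mode: str) -> PartitionPlan:
    """Plan the three-way row partition of an L-row profile.

    The first two parts have floor(L/3) rows; the third takes the
    remainder, L - 2*floor(L/3). Boundaries are half-open and 0-based.
    """
    if mode not in PARTITION_MODES:
        raise ValueError(f"unknown partition mode {mode!r}; expected one of {PARTITION_MODES}")
    if length < 3:
        raise ValueError(f"sequence too short to partition: L={length} < 3")
    base = length // 3
    boundaries = ((0, base), (base, 2 * base), (2 * base, length))
    return PartitionPlan(mode=mode, boundaries=boundaries)


def partition_rows(pssm: PSSMMatrix, plan: PartitionPlan) -> list[np.ndarray]:
    """Return the three row blocks of ``pssm`` according to ``plan``."""
    if plan.boundaries[-1][1] != pssm.length:
        raise ValueError(
            f"partition plan covers {plan.boundaries[-1][1]} rows "
            f"but PSSM has {pssm.length}"
        )
    return [pssm.scores[start:stop] for start, stop in plan.boundaries]


def write_normalized_tsv(pssm: PSSMMatrix, path: str | Path) -> None:
    """Dump a normalized profile as TSV (1-based position, residue, 20 columns)."""
    if not pssm.normalized:
        raise ValueError("refusing to dump an unnormalized PSSM as a normalized TSV")
    with open(path, "w") as fh:
        fh.write("pos\tresidue\t" + "\t".join(PSSM_ALPHABET) + "\n")
        for i in range(pssm.length):
            values = "\t".join(f"{v:.10g}" for v in pssm.scores[i])
            fh.write(f"{i + 1}\t{pssm.residue_column[i]}\t{values}\n")
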
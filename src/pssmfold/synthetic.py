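"""Seeded synthetic PSSM datasets with controllable class structure.

Two independent class signals are available, chosen so each one is visible
to exactly one feature family:

* ``mean_signal`` — class-specific column-mean profiles.  Mean-centering
  makes the ACC covariances blind to pure column shifts, while the
  uncentered separated-dimer sums respond strongly; this is the SD-targeted
  signal.
* ``lag_signal`` — class-specific residue-pair coupling at lag 1: for a few
  ordered column pairs (m, n) a shared latent value is added at positions i
  and i+1.  Cross-covariance at lag 1 picks this up; at the default dimer
  separation k=4 the coupling contributes no lag-k covariance and no mean
  shift, so SD features carry essentially none of it.

All signal lives in the score matrices.  The "sequences" are i.i.d. letters
that exist only to satisfy the file formats, since every feature formula
reads scores alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FeatureConfig
from .pssm_io import PSIBLAST_COLUMNS, PSSMProfile, serialize_pssm

SCORE_MIN, SCORE_MAX = -10, 12

#: separation preset -> (column mean shift, coupling latent s.d.)
SEPARATION_PRESETS: dict[str, tuple[float, float]] = {
    "low": (0.0, 0.0),
    "medium": (1.0, 2.0),
    "high": (2.0, 3.5),
}

_COUPLED_PAIRS_PER_CLASS = 4


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated dataset; fully reproducible from ``seed``."""

    n_classes: int = 3
    n_per_class: int = 40
    length_range: tuple[int, int] = (30, 60)
    separation: str = "high"
    noise_sd: float = 2.0
    seed: int = 0
    mean_signal: bool = True
    lag_signal: bool = True

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_per_class < 1:
            raise ValueError("need at least 1 protein per class")
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError(f"invalid length range ({lo}, {hi})")
        if self.separation not in SEPARATION_PRESETS:
            raise ValueError(
                f"unknown separation {self.separation!r}; "
                f"choose from {sorted(SEPARATION_PRESETS)}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_dataset(
    spec: SyntheticSpec, cfg: FeatureConfig | None = None
) -> tuple[list[PSSMProfile], list[str]]:
    """Draw ``n_classes * n_per_class`` labeled profiles.

    Scores are rounded to integers in PSI-BLAST's typical range so the
    fixtures stay within the ASCII dialect.
    """
    cfg = cfg or FeatureConfig()
    lo, hi = spec.length_range
    if lo <= max(cfg.lg, cfg.k):
        raise ValueError(
            f"minimum length {lo} must exceed max(LG, k) = {max(cfg.lg, cfg.k)}"
        )
    mean_shift, coupling_sd = SEPARATION_PRESETS[spec.separation]
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(PSIBLAST_COLUMNS))

    class_means = []
    class_pairs = []
    for _ in range(spec.n_classes):
        pattern = rng.choice([-1.0, 0.0, 1.0], size=20)
        class_means.append(pattern * mean_shift if spec.mean_signal else np.zeros(20))
        flat = rng.choice(400, size=_COUPLED_PAIRS_PER_CLASS, replace=False)
        class_pairs.append([(int(f) // 20, int(f) % 20) for f in flat])

    profiles: list[PSSMProfile] = []
    labels: list[str] = []
    for c in range(spec.n_classes):
        label = f"fold{c + 1}"
        for i in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            x = rng.normal(0.0, spec.noise_sd, size=(length, 20))
            x += class_means[c]
            if spec.lag_signal and coupling_sd > 0:
                for m, n in class_pairs[c]:
                    z = rng.normal(0.0, coupling_sd, size=length - 1)
                    x[:-1, m] += z
                    x[1:, n] += z
            scores = np.clip(np.rint(x), SCORE_MIN, SCORE_MAX)
            seq = "".join(rng.choice(letters, size=length))
            profiles.append(
                PSSMProfile(
                    protein_id=f"C{c + 1}P{i + 1:03d}",
                    sequence=seq,
                    scores=scores,
                )
            )
            labels.append(label)
    return profiles, labels


def write_fixture(
    profiles: list[PSSMProfile], labels: list[str], directory
) -> dict[str, Path]:
    """Write one ASCII PSSM per protein plus a FASTA and a label TSV.

    Exercises the same three formats the parser consumes, so parse
    round-trips recover the generated profiles exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not directory.is_dir():
        raise ValueError(f"not a writable directory: {directory}")
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels must align")

    pssm_dir = directory / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for p in profiles:
        (pssm_dir / f"{p.protein_id}.pssm").write_text(serialize_pssm(p))

    fasta_path = directory / "sequences.fasta"
    with fasta_path.open("w") as fh:
        for p in profiles:
            fh.write(f">{p.protein_id}\n")
            for start in range(0, len(p.sequence), 60):
                fh.write(p.sequence[start:start + 60] + "\n")

    labels_path = directory / "labels.tsv"
    with labels_path.open("w") as fh:
        for p, lab in zip(profiles, labels):
            fh.write(f"{p.protein_id}\t{lab}\n")

    return {"pssm_dir": pssm_dir, "fasta": fasta_path, "labels": labels_path}
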
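"""Synthetic stimulus environments for language games.

Stimuli are points in CIE LAB space (lightness L, opponent axes a and b);
distances between stimuli are plain Euclidean distances in (L, a, b).  The
chip universe is a jittered grid over a fixed LAB box standing in for a
Munsell chip table; a real chip table can be supplied as a CSV with header
``L,a,b``.  Frequency-biased environments are built by resampling the chip
universe with trivariate-normal weights around a focal color, giving a
family-resemblance structure: the same chips occur in both environments but
with different frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ChipSet",
    "Environment",
    "DiscreteEnvironment",
    "GameContext",
    "DegenerateEnvironmentError",
    "FOCAL_A",
    "FOCAL_B",
    "default_sigma",
    "generate_base_chipset",
    "load_chipset_csv",
    "save_chipset_csv",
    "make_weighted_environment",
    "sample_context",
    "sample_discrete_context",
    "make_discrete_environment_pair",
    "MIN_PAIR_DISTANCE",
]

#: Minimum Euclidean LAB distance between any two stimuli of a game context.
MIN_PAIR_DISTANCE = 50.0

#: Focal colors of the two frequency-biased environments, in LAB.
FOCAL_A = np.array([66.97, 18.65, 38.36])
FOCAL_B = np.array([46.24, -16.46, -1.41])

# LAB box covered by the generated chip universe.
_L_RANGE = (10.0, 95.0)
_AB_RANGE = (-80.0, 80.0)


class DegenerateEnvironmentError(RuntimeError):
    """Raised when no valid game context can be sampled from an environment."""


@dataclass(frozen=True)
class ChipSet:
    """An ordered universe of color chips, shape (n, 3) in LAB."""

    chips: np.ndarray
    provenance: str = "generated"

    def __post_init__(self) -> None:
        chips = np.asarray(self.chips, dtype=float)
        if chips.ndim != 2 or chips.shape[1] != 3:
            raise ValueError("chips must be an (n, 3) array of LAB points")
        if len(chips) == 0:
            raise ValueError("chip set must be non-empty")
        if not np.isfinite(chips).all():
            raise ValueError("chips must be finite")
        if len(np.unique(chips, axis=0)) != len(chips):
            raise ValueError("chip set contains duplicate chips")
        object.__setattr__(self, "chips", chips)

    def __len__(self) -> int:
        return len(self.chips)


@dataclass(frozen=True)
class Environment:
    """A multiset of stimuli from which game contexts are drawn.

    ``chips`` may contain repeats when the environment was produced by
    frequency-weighted resampling; ``focal`` is the center of the weighting
    distribution, absent for the uniform base environment.
    """

    chips: np.ndarray
    label: str = "base"
    focal: np.ndarray | None = None
    meta: dict | None = None

    def __post_init__(self) -> None:
        chips = np.asarray(self.chips, dtype=float)
        if chips.ndim != 2 or chips.shape[1] != 3:
            raise ValueError("chips must be an (n, 3) array")
        object.__setattr__(self, "chips", chips)
        if self.focal is not None:
            object.__setattr__(self, "focal", np.asarray(self.focal, dtype=float))

    def __len__(self) -> int:
        return len(self.chips)


@dataclass(frozen=True)
class DiscreteEnvironment:
    """A set of opaque stimulus identifiers for the ungrounded naming game."""

    stimuli: tuple[str, ...]
    label: str = "A"

    def __post_init__(self) -> None:
        if len(set(self.stimuli)) != len(self.stimuli):
            raise ValueError("discrete stimuli must be distinct")

    def __len__(self) -> int:
        return len(self.stimuli)


@dataclass(frozen=True)
class GameContext:
    """Four stimuli, one of which (``topic_index``) is the topic.

    ``stimuli`` is a (4, 3) LAB array for grounded games or a 4-tuple of
    identifiers for the discrete naming game.
    """

    stimuli: object
    topic_index: int

    def __post_init__(self) -> None:
        if not 0 <= self.topic_index <= 3:
            raise ValueError("topic_index must lie in [0, 3]")

    @property
    def topic(self):
        return self.stimuli[self.topic_index]

    def distractor_indices(self) -> list[int]:
        return [i for i in range(4) if i != self.topic_index]


def default_sigma(scale_rule: str = "per-dimension") -> np.ndarray:
    """Per-dimension scales of the environment weighting distributions.

    The scale is 10 times the difference between the two focal colors:
    per dimension by default, or 10 times the Euclidean focal distance
    applied to all three dimensions with ``scale_rule="euclidean"``.
    """
    if scale_rule == "per-dimension":
        return 10.0 * np.abs(FOCAL_A - FOCAL_B)
    if scale_rule == "euclidean":
        return np.full(3, 10.0 * float(np.linalg.norm(FOCAL_A - FOCAL_B)))
    raise ValueError(f"unknown scale_rule: {scale_rule!r}")


def generate_base_chipset(n_chips: int = 1269, seed: int = 0) -> ChipSet:
    """Generate ``n_chips`` distinct chips on a jittered grid over the LAB box.

    Deterministic for a fixed seed.  The grid is sized so that jitter (half a
    grid step, uniform) can never collide two chips.
    """
    if n_chips < 4:
        raise ValueError("n_chips must be at least 4")
    rng = np.random.default_rng(seed)
    # Smallest grid with at least n_chips cells, roughly cubic.
    per_side = int(np.ceil(n_chips ** (1.0 / 3.0)))
    while per_side**3 < n_chips:
        per_side += 1
    axes = [
        np.linspace(lo, hi, per_side)
        for lo, hi in (_L_RANGE, _AB_RANGE, _AB_RANGE)
    ]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = rng.choice(len(grid), size=n_chips, replace=False)
    keep.sort()
    chips = grid[keep]
    steps = np.array([(hi - lo) / max(per_side - 1, 1) for lo, hi in
                      (_L_RANGE, _AB_RANGE, _AB_RANGE)])
    chips = chips + rng.uniform(-0.49, 0.49, size=chips.shape) * steps
    return ChipSet(chips=chips, provenance="generated")


def load_chipset_csv(path: str | Path) -> ChipSet:
    """Load a user-supplied chip table (CSV with header ``L,a,b``)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"L", "a", "b"} - set(df.columns)
    if missing:
        raise ValueError(f"chip table missing columns: {sorted(missing)}")
    return ChipSet(chips=df[["L", "a", "b"]].to_numpy(float),
                   provenance="user-supplied")


def save_chipset_csv(chips: np.ndarray, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(np.asarray(chips, float), columns=["L", "a", "b"]).to_csv(
        path, index=False)


def make_weighted_environment(
    base: ChipSet,
    focal: np.ndarray,
    sigma_per_dim: np.ndarray | None = None,
    n_env: int = 600,
    seed: int = 0,
    label: str = "A",
    mode: str = "resample",
) -> Environment:
    """Draw a frequency-biased environment around a focal color.

    With ``mode="resample"`` (default), ``n_env`` chips are drawn from the
    base chip set with replacement, chip ``c`` weighted proportionally to
    ``exp(-sum_d (c_d - focal_d)^2 / (2 sigma_d^2))`` — uncorrelated
    trivariate-normal weights.  With ``mode="gaussian"`` the chips are drawn
    directly from that normal distribution instead of from the chip table.
    """
    if len(base) == 0:
        raise ValueError("base chip set is empty")
    if n_env < 1:
        raise ValueError("n_env must be positive")
    focal = np.asarray(focal, dtype=float)
    sigma = default_sigma() if sigma_per_dim is None else np.asarray(
        sigma_per_dim, dtype=float)
    if (sigma <= 0).any():
        raise ValueError("sigma components must be positive")
    rng = np.random.default_rng(seed)
    if mode == "gaussian":
        chips = rng.normal(loc=focal, scale=sigma, size=(n_env, 3))
    elif mode == "resample":
        log_w = -0.5 * (((base.chips - focal) / sigma) ** 2).sum(axis=1)
        w = np.exp(log_w - log_w.max())
        w /= w.sum()
        idx = rng.choice(len(base), size=n_env, replace=True, p=w)
        chips = base.chips[idx]
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    meta = {"sigma": [float(s) for s in sigma], "seed": int(seed),
            "mode": mode}
    return Environment(chips=chips, label=label, focal=focal, meta=meta)


def sample_context(
    env: Environment,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> GameContext:
    """Rejection-sample a 4-stimulus context with all pairwise distances > 50.

    Raises :class:`DegenerateEnvironmentError` if no admissible draw is found
    within ``max_attempts`` attempts.
    """
    chips = env.chips
    if len(chips) < 4:
        raise DegenerateEnvironmentError(
            "environment holds fewer than 4 stimuli")
    for _ in range(max_attempts):
        idx = rng.choice(len(chips), size=4, replace=False)
        four = chips[idx]
        d2 = ((four[:, None, :] - four[None, :, :]) ** 2).sum(-1)
        iu = np.triu_indices(4, 1)
        if (d2[iu] > MIN_PAIR_DISTANCE**2).all():
            return GameContext(stimuli=four,
                               topic_index=int(rng.integers(4)))
    raise DegenerateEnvironmentError(
        f"no valid context found in {max_attempts} attempts")


def sample_discrete_context(
    env: DiscreteEnvironment,
    rng: np.random.Generator,
) -> GameContext:
    """Sample 4 distinct discrete stimuli and a uniform topic."""
    if len(env) < 4:
        raise DegenerateEnvironmentError(
            "discrete environment holds fewer than 4 stimuli")
    idx = rng.choice(len(env), size=4, replace=False)
    four = tuple(env.stimuli[i] for i in idx)
    return GameContext(stimuli=four, topic_index=int(rng.integers(4)))


def make_discrete_environment_pair(
    n_stimuli: int = 16,
    n_shared: int = 5,
    seed: int = 0,
) -> tuple[DiscreteEnvironment, DiscreteEnvironment]:
    """Two discrete environments of ``n_stimuli`` sharing ``n_shared`` ids."""
    if not 0 <= n_shared <= n_stimuli:
        raise ValueError("n_shared must lie in [0, n_stimuli]")
    rng = np.random.default_rng(seed)
    n_total = 2 * n_stimuli - n_shared
    ids = [f"s{i:03d}" for i in range(n_total)]
    perm = rng.permutation(n_total)
    shared = [ids[i] for i in perm[:n_shared]]
    only_a = [ids[i] for i in perm[n_shared:n_stimuli]]
    only_b = [ids[i] for i in perm[n_stimuli:]]
    env_a = DiscreteEnvironment(stimuli=tuple(sorted(shared + only_a)),
                                label="A")
    env_b = DiscreteEnvironment(stimuli=tuple(sorted(shared + only_b)),
                                label="B")
    return env_a, env_b


def save_environment(env: Environment, csv_path: str | Path) -> None:
    """Write an environment as L,a,b CSV plus a JSON sidecar of metadata."""
    csv_path = Path(csv_path)
    save_chipset_csv(env.chips, csv_path)
    meta = {
        "label": env.label,
        "focal": None if env.focal is None else list(map(float, env.focal)),
        "n_chips": int(len(env)),
        **(env.meta or {}),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_environment(csv_path: str | Path) -> Environment:
    import pandas as pd

    csv_path = Path(csv_path)
    chips = pd.read_csv(csv_path)[["L", "a", "b"]].to_numpy(float)
    label, focal, extra = "base", None, None
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.pop("label", "base")
        focal = meta.pop("focal", None)
        meta.pop("n_chips", None)
        extra = meta or None
    return Environment(chips=chips, label=label,
                       focal=None if focal is None else np.asarray(focal),
                       meta=extra)


def save_discrete_environment(env: DiscreteEnvironment,
                              path: str | Path) -> None:
    Path(path).write_text("\n".join(env.stimuli) + "\n")


def load_discrete_environment(path: str | Path,
                              label: str = "A") -> DiscreteEnvironment:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    return DiscreteEnvironment(stimuli=tuple(lines), label=label)
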
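"""Token-set search spaces and bit-string genomes.

A candidate population-PK model is encoded as a fixed-length bit string.  The
string is partitioned into groups, one per *token set*: a group of mutually
exclusive model-structure options (compartment count, a covariate effect and
its functional form, a BSV term, the residual-error model, ...).  Each option
carries the number of *effects* it adds (one additional estimated parameter
tied to a covariate or feature counts as one effect) and the number of extra
estimated parameters it introduces.

Bit groups are read as plain binary; out-of-range values wrap by ``v mod k``
so that decoding is total on all ``2**n`` genomes.

The sampler supports an *effect limit*: per-option selection probabilities are
exponentially tilted in the option's effect count, with the tilt calibrated by
bisection (against an exact dynamic-programming convolution of the total-effect
distribution) so that a target fraction — 80% by default — of raw candidate
models falls at or under the limit.  Models exceeding the limit are then
discarded and replaced before evaluation, so no evaluated model ever exceeds
the limit; the 80% figure is a property of the raw generator only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError

Genome = tuple[int, ...]

__all__ = [
    "Genome",
    "TokenOption",
    "TokenSet",
    "SearchSpace",
    "Phenotype",
    "decode",
    "count_effects",
    "encode",
    "hamming",
    "one_bit_neighbors",
    "two_bit_neighbors",
    "effect_distribution",
    "within_limit_probability",
    "calibrate_tilt",
    "GenomeSampler",
    "sample_population",
    "load_search_space",
    "search_space_from_dict",
    "search_space_to_dict",
]


@dataclass(frozen=True)
class TokenOption:
    """One mutually exclusive choice within a token set.

    ``payload`` is the structured description consumed by the model builder
    (e.g. ``{"n_compartments": 2}`` or
    ``{"covariate": {"parameter": "CL", "covariate": "WT", "form": "power"}}``).
    A "none/absent" option has ``n_effects == 0``.
    """

    label: str
    payload: Mapping[str, Any] = field(default_factory=dict)
    n_effects: int = 0
    n_extra_params: int = 0

    def __post_init__(self) -> None:
        if self.n_effects < 0 or self.n_extra_params < 0:
            raise ConfigurationError(
                f"option {self.label!r}: n_effects and n_extra_params must be >= 0"
            )


@dataclass(frozen=True)
class TokenSet:
    """An ordered group of mutually exclusive options occupying one bit group."""

    name: str
    options: tuple[TokenOption, ...]

    def __post_init__(self) -> None:
        if len(self.options) < 1:
            raise ConfigurationError(f"token set {self.name!r} has no options")
        labels = [o.label for o in self.options]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"token set {self.name!r} has duplicate labels")

    @property
    def k(self) -> int:
        return len(self.options)

    @property
    def n_bits(self) -> int:
        """Smallest b with 2**b >= k (0 when the set has a single option)."""
        return int(np.ceil(np.log2(self.k))) if self.k > 1 else 0


@dataclass(frozen=True)
class SearchSpace:
    """An ordered sequence of token sets plus an optional effect limit.

    Token sets occupy the genome in declaration order.
    """

    token_sets: tuple[TokenSet, ...]
    effect_limit: int | None = None

    def __post_init__(self) -> None:
        if not self.token_sets:
            raise ConfigurationError("search space needs at least one token set")
        if self.effect_limit is not None and self.effect_limit < 1:
            raise ConfigurationError("effect_limit must be >= 1 when set")

    @property
    def n_total_bits(self) -> int:
        return sum(ts.n_bits for ts in self.token_sets)

    @property
    def bit_slices(self) -> tuple[slice, ...]:
        out, pos = [], 0
        for ts in self.token_sets:
            out.append(slice(pos, pos + ts.n_bits))
            pos += ts.n_bits
        return tuple(out)

    def enumerate_genomes(self) -> Iterator[Genome]:
        """All 2**n genomes; intended for tiny benchmark spaces only."""
        n = self.n_total_bits
        for v in range(2**n):
            yield tuple((v >> (n - 1 - i)) & 1 for i in range(n))


@dataclass(frozen=True)
class Phenotype:
    """Decoded genome: one chosen option index per token set."""

    choices: tuple[int, ...]
    total_effects: int
    total_extra_params: int

    def options(self, space: SearchSpace) -> tuple[TokenOption, ...]:
        return tuple(
            ts.options[i] for ts, i in zip(space.token_sets, self.choices)
        )


def _group_value(bits: Sequence[int], sl: slice) -> int:
    v = 0
    for b in bits[sl]:
        v = (v << 1) | int(b)
    return v


def decode(space: SearchSpace, genome: Sequence[int]) -> Phenotype:
    """Decode a genome into per-set option choices (big-endian binary, mod k)."""
    bits = tuple(int(b) for b in genome)
    if len(bits) != space.n_total_bits:
        raise ValueError(
            f"genome length {len(bits)} != search-space length {space.n_total_bits}"
        )
    if any(b not in (0, 1) for b in bits):
        raise ValueError("genome bits must be 0/1")
    choices = []
    for ts, sl in zip(space.token_sets, space.bit_slices):
        v = _group_value(bits, sl)
        choices.append(v % ts.k)
    chosen = [ts.options[i] for ts, i in zip(space.token_sets, choices)]
    return Phenotype(
        choices=tuple(choices),
        total_effects=sum(o.n_effects for o in chosen),
        total_extra_params=sum(o.n_extra_params for o in chosen),
    )


def count_effects(phenotype: Phenotype) -> int:
    """Total effect count of a decoded model (sum over chosen options)."""
    return phenotype.total_effects


def encode(space: SearchSpace, choices: Sequence[int]) -> Genome:
    """Canonical genome for a choice vector (smallest representation per group)."""
    if len(choices) != len(space.token_sets):
        raise ValueError("one choice per token set required")
    bits: list[int] = []
    for ts, i in zip(space.token_sets, choices):
        if not 0 <= i < ts.k:
            raise ValueError(f"choice {i} out of range for token set {ts.name!r}")
        bits.extend((i >> (ts.n_bits - 1 - j)) & 1 for j in range(ts.n_bits))
    return tuple(bits)


# ---------------------------------------------------------------------------
# Neighborhoods


def hamming(a: Sequence[int], b: Sequence[int]) -> int:
    if len(a) != len(b):
        raise ValueError("genomes differ in length")
    return sum(x != y for x, y in zip(a, b))


def one_bit_neighbors(genome: Sequence[int]) -> list[Genome]:
    """All n genomes at Hamming distance 1."""
    g = tuple(int(b) for b in genome)
    return [g[:i] + (1 - g[i],) + g[i + 1:] for i in range(len(g))]


def two_bit_neighbors(genome: Sequence[int]) -> list[Genome]:
    """All n(n-1)/2 genomes at Hamming distance 2 (empty when n < 2)."""
    g = tuple(int(b) for b in genome)
    out = []
    for i, j in combinations(range(len(g)), 2):
        h = list(g)
        h[i], h[j] = 1 - h[i], 1 - h[j]
        out.append(tuple(h))
    return out


# ---------------------------------------------------------------------------
# Effect-limit sampling


def _tilted_probs(ts: TokenSet, lam: float) -> np.ndarray:
    """Selection probabilities within one token set, tilted by exp(-lam * effects)."""
    e = np.array([o.n_effects for o in ts.options], dtype=float)
    w = np.exp(-lam * (e - e.min()))  # shift for numerical stability
    return w / w.sum()


def effect_distribution(space: SearchSpace, lam: float = 0.0) -> np.ndarray:
    """Exact distribution of total effects under the tilted per-set sampler.

    Dynamic-programming convolution over token sets; entry ``p[e]`` is
    P(total effects == e).
    """
    max_total = sum(max(o.n_effects for o in ts.options) for ts in space.token_sets)
    p = np.zeros(max_total + 1)
    p[0] = 1.0
    for ts in space.token_sets:
        probs = _tilted_probs(ts, lam)
        q = np.zeros_like(p)
        for opt, pr in zip(ts.options, probs):
            q[opt.n_effects:] += pr * p[: len(p) - opt.n_effects or None]
        p = q
    return p


def within_limit_probability(
    space: SearchSpace, lam: float, limit: int | None = None
) -> float:
    """P(total effects <= limit) for a raw (pre-discard) tilted draw."""
    if limit is None:
        limit = space.effect_limit
    if limit is None:
        return 1.0
    p = effect_distribution(space, lam)
    return float(p[: min(limit, len(p) - 1) + 1].sum())


def calibrate_tilt(
    space: SearchSpace,
    target_within: float = 0.80,
    limit: int | None = None,
    tol: float = 1e-10,
) -> float:
    """Tilt strength lambda with P(total effects <= limit) == target_within.

    P is non-decreasing in lambda (larger lambda favours low-effect options),
    so a plain bisection suffices.  The tilt is sign-unrestricted: when the
    untilted sampler already lands more than the target fraction within the
    limit, a negative lambda (favouring effects) brings it down to the target.
    Returns 0.0 when every option combination is within the limit (nothing to
    calibrate); raises :class:`ConfigurationError` when no combination is.
    """
    if limit is None:
        limit = space.effect_limit
    if limit is None:
        return 0.0
    min_total = sum(min(o.n_effects for o in ts.options) for ts in space.token_sets)
    max_total = sum(max(o.n_effects for o in ts.options) for ts in space.token_sets)
    if min_total > limit:
        raise ConfigurationError(
            f"effect limit {limit} infeasible: minimum achievable total is {min_total}"
        )
    if max_total <= limit:
        return 0.0
    lo, hi = -1.0, 1.0
    while within_limit_probability(space, lo, limit) > target_within and lo > -512:
        lo *= 2
    while within_limit_probability(space, hi, limit) < target_within and hi < 512:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if within_limit_probability(space, mid, limit) < target_within:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


class GenomeSampler:
    """Random-genome generator honouring a search space's effect limit.

    Without an effect limit every option index is sampled uniformly (and the
    bit pattern uniformly among the patterns decoding to that index).  With a
    limit, per-set option probabilities are tilted so that ``target_within``
    of *raw* draws satisfy the limit; :meth:`sample` then discards and
    replaces any draw exceeding the limit, so its output always satisfies it.

    Attributes
    ----------
    lam_ : float
        Calibrated tilt strength (0 when no limit is set).
    raw_within_prob_ : float
        Exact P(total effects <= limit) of the raw generator.
    n_raw_draws_, n_discarded_ : int
        Bookkeeping counters over all :meth:`sample` calls.
    """

    def __init__(self, space: SearchSpace, target_within: float = 0.80):
        self.space = space
        self.target_within = target_within
        self.lam_ = calibrate_tilt(space, target_within)
        self.raw_within_prob_ = within_limit_probability(space, self.lam_)
        self._probs = [_tilted_probs(ts, self.lam_) for ts in space.token_sets]
        self.n_raw_draws_ = 0
        self.n_discarded_ = 0

    def _draw(self, rng: np.random.Generator) -> Genome:
        bits: list[int] = []
        for ts, probs in zip(self.space.token_sets, self._probs):
            idx = int(rng.choice(ts.k, p=probs))
            # uniform choice among the bit patterns decoding to idx (mod k)
            n_rep = ((1 << ts.n_bits) - 1 - idx) // ts.k + 1 if ts.n_bits else 1
            v = idx + ts.k * int(rng.integers(n_rep))
            bits.extend((v >> (ts.n_bits - 1 - j)) & 1 for j in range(ts.n_bits))
        return tuple(bits)

    def sample_raw(self, n: int, rng: np.random.Generator) -> list[Genome]:
        """n raw draws, no discard — the generator whose within-limit fraction
        is calibrated to ``target_within``."""
        self.n_raw_draws_ += n
        return [self._draw(rng) for _ in range(n)]

    def sample(self, n: int, rng: np.random.Generator) -> list[Genome]:
        """n genomes all satisfying the effect limit (discard-and-replace)."""
        limit = self.space.effect_limit
        out: list[Genome] = []
        while len(out) < n:
            g = self._draw(rng)
            self.n_raw_draws_ += 1
            if limit is not None and decode(self.space, g).total_effects > limit:
                self.n_discarded_ += 1
                continue
            out.append(g)
        return out

    def replace_if_over_limit(
        self, genome: Genome, rng: np.random.Generator
    ) -> Genome:
        """Pass the genome through unless it exceeds the limit; then resample."""
        limit = self.space.effect_limit
        if limit is None or decode(self.space, genome).total_effects <= limit:
            return genome
        return self.sample(1, rng)[0]


def within_effect_limit(space: SearchSpace, genome: Sequence[int]) -> bool:
    """True when the genome's decoded total effects satisfy the space's limit."""
    if space.effect_limit is None:
        return True
    return decode(space, genome).total_effects <= space.effect_limit


def sample_population(
    space: SearchSpace,
    n: int,
    target_within: float = 0.80,
    rng_seed: int | np.random.Generator = 0,
) -> list[Genome]:
    """n genomes under the effect limit (uniform when no limit is set)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return GenomeSampler(space, target_within).sample(n, rng)


# ---------------------------------------------------------------------------
# Search-space definition files


def search_space_from_dict(d: Mapping[str, Any]) -> SearchSpace:
    """Build and validate a search space from a parsed YAML/JSON mapping."""
    if "token_sets" not in d:
        raise ConfigurationError("search-space definition needs a 'token_sets' list")
    sets = []
    for ts in d["token_sets"]:
        if "name" not in ts or "options" not in ts:
            raise ConfigurationError("each token set needs 'name' and 'options'")
        opts = []
        for o in ts["options"]:
            if "label" not in o:
                raise ConfigurationError(
                    f"token set {ts['name']!r}: every option needs a 'label'"
                )
            opts.append(
                TokenOption(
                    label=str(o["label"]),
                    payload=dict(o.get("payload", {})),
                    n_effects=int(o.get("n_effects", 0)),
                    n_extra_params=int(o.get("n_extra_params", 0)),
                )
            )
        sets.append(TokenSet(name=str(ts["name"]), options=tuple(opts)))
    limit = d.get("effect_limit")
    return SearchSpace(
        token_sets=tuple(sets),
        effect_limit=None if limit in (None, "unlimited") else int(limit),
    )


def search_space_to_dict(space: SearchSpace) -> dict[str, Any]:
    return {
        "effect_limit": space.effect_limit,
        "token_sets": [
            {
                "name": ts.name,
                "options": [
                    {
                        "label": o.label,
                        "payload": dict(o.payload),
                        "n_effects": o.n_effects,
                        "n_extra_params": o.n_extra_params,
                    }
                    for o in ts.options
                ],
            }
            for ts in space.token_sets
        ],
    }


def load_search_space(path: str) -> SearchSpace:
    """Load a YAML/JSON search-space definition file."""
    with open(path) as fh:
        return search_space_from_dict(yaml.safe_load(fh))
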
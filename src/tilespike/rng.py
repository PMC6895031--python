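"""Xorshift32 pseudo-random streams.

All randomness in the package — neuron placement, bias currents, Bernoulli
connection draws, log-normal weights — flows through Marsaglia's 32-bit
xorshift generator (shift triplet 13, 17, 5).  The generator is tiny,
bit-exact across platforms, and cheap to fork into independent substreams,
which is what makes serial, parallel and monolithic runs of the same model
byte-identical.

A stream never holds state zero (zero is a fixed point of the recurrence);
seeds are mixed through SplitMix64 before use so that small consecutive
user seeds yield decorrelated streams.
"""

from __future__ import annotations

import math

import numpy as np

_MASK32 = 0xFFFFFFFF
_MASK64 = 0xFFFFFFFFFFFFFFFF
_INV_2_32 = 2.0 ** -32


def xorshift32_next(word: int) -> int:
    """One step of the xorshift32 recurrence (13, 17, 5).

    ``word`` must be a nonzero 32-bit unsigned integer; returns the next
    nonzero 32-bit state, which doubles as the output.
    """
    word ^= (word << 13) & _MASK32
    word ^= word >> 17
    word ^= (word << 5) & _MASK32
    return word


def _splitmix64(state: int) -> tuple[int, int]:
    state = (state + 0x9E3779B97F4A7C15) & _MASK64
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31), state


def derive_stream_seed(seed: int, *keys: int) -> int:
    """Derive a nonzero 32-bit substream seed from a master seed and keys.

    Used to give every tile (and every purpose within a tile: placement,
    connectivity, weights) its own decorrelated xorshift stream while keeping
    the whole build a pure function of the master seed.
    """
    state = (seed & _MASK64) ^ 0xA5A5A5A55A5A5A5A
    out = 0
    for k in (1,) + tuple(keys):
        state = (state ^ ((k & _MASK64) * 0xFF51AFD7ED558CCD)) & _MASK64
        out, state = _splitmix64(state)
    word = (out ^ (out >> 32)) & _MASK32
    if word == 0:  # measure-zero corner; any fixed nonzero value works
        word = 0x1A2B3C4D
    return word


class Xorshift32:
    """A seeded xorshift32 stream with uniform/normal/Poisson adapters.

    Parameters
    ----------
    seed:
        Nonzero 32-bit seed.  Zero is rejected because it is a fixed point
        of the recurrence and would freeze the stream.
    """

    __slots__ = ("_state",)

    def __init__(self, seed: int):
        seed = int(seed)
        if seed == 0:
            raise ValueError("xorshift32 seed must be nonzero")
        if not 0 < (seed & _MASK32):
            raise ValueError("xorshift32 seed must be a nonzero 32-bit value")
        self._state = seed & _MASK32

    @classmethod
    def substream(cls, seed: int, *keys: int) -> "Xorshift32":
        """Stream keyed by (master seed, keys...), e.g. (seed, PLACE, tile_id)."""
        return cls(derive_stream_seed(seed, *keys))

    @property
    def state(self) -> int:
        return self._state

    def next_word(self) -> int:
        self._state = xorshift32_next(self._state)
        return self._state

    def uniform(self) -> float:
        """One uniform in (0, 1); never exactly 0 (state is never 0)."""
        return self.next_word() * _INV_2_32

    def uniforms(self, n: int) -> np.ndarray:
        """``n`` uniforms in (0, 1) as a float64 array."""
        out = np.empty(int(n))
        x = self._state
        for i in range(int(n)):
            x ^= (x << 13) & _MASK32
            x ^= x >> 17
            x ^= (x << 5) & _MASK32
            out[i] = x
        self._state = x
        out *= _INV_2_32
        return out

    def normal(self, mean: float = 0.0, sd: float = 1.0) -> float:
        return float(self.normals(1, mean, sd)[0])

    def normals(self, n: int, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
        """``n`` normal deviates via Box–Muller.

        Consumes ``2*ceil(n/2)`` uniforms; the spare deviate of an odd draw
        is discarded so the stream position depends only on ``n``.
        """
        n = int(n)
        m = (n + 1) // 2
        u = self.uniforms(2 * m)
        r = np.sqrt(-2.0 * np.log(u[:m]))
        theta = 2.0 * math.pi * u[m:]
        z = np.concatenate([r * np.cos(theta), r * np.sin(theta)])[:n]
        return mean + sd * z

    def poisson(self, lam: float) -> int:
        """A Poisson count with mean ``lam``.

        Knuth's product method below λ = 50; above that, a rounded normal
        approximation (error is negligible at the λ ~ 10³–10⁴ used for
        per-type neuron counts).
        """
        if lam < 0:
            raise ValueError("Poisson mean must be >= 0")
        if lam == 0:
            return 0
        if lam < 50.0:
            limit = math.exp(-lam)
            k, prod = 0, self.uniform()
            while prod > limit:
                prod *= self.uniform()
                k += 1
            return k
        return max(0, int(round(self.normal(lam, math.sqrt(lam)))))
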
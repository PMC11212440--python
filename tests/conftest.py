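"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they check:
Spearman is recomputed from O(n²) counting ranks and an explicit Pearson
sum, and the prediction equations are re-evaluated with sympy
arbitrary-precision arithmetic directly from their printed closed forms.
"""

from __future__ import annotations

import math

import pytest
import sympy as sp

from natriuria import Anthropometry, SpotSample


@pytest.fixture
def male_60() -> Anthropometry:
    return Anthropometry(sex="male", age=60, weight=80, height=170)


@pytest.fixture
def spot_am() -> SpotSample:
    return SpotSample(timing="AM", una=100.0, ucrea_mg_dl=100.0, uk=50.0)


# ---------------------------------------------------------------------------
# Brute-force Spearman oracle: average ranks by O(n²) pair counting, then an
# explicit Pearson correlation of the ranks.


def counting_ranks(v):
    return [
        1.0
        + sum(1 for w in v if w < x)
        + 0.5 * (sum(1 for w in v if w == x) - 1)
        for x in v
    ]


def spearman_bruteforce(x, y):
    rx, ry = counting_ranks(list(x)), counting_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    if sxx == 0 or syy == 0:
        return math.nan
    return sxy / math.sqrt(sxx * syy)


# ---------------------------------------------------------------------------
# Arbitrary-precision re-evaluation of the printed closed forms, 50 working
# digits via mpmath (sympy's precision backend) on exact rational inputs.

_mp = sp.mpmath if hasattr(sp, "mpmath") else __import__("mpmath")
_mp.mp.dps = 50
_R = sp.Rational


def _dec(x):
    # exact rational from a decimal literal, as an mpmath 50-digit value
    r = _R(str(x))
    return _mp.mpf(r.p) / _mp.mpf(r.q)


def kawasaki_oracle(sex, age, weight, height, una, ucrea_mg_dl) -> float:
    if sex == "male":
        body = _dec(15.12) * _dec(weight) + _dec(7.39) * _dec(height) \
            - _dec(12.63) * _dec(age) - _dec(79.9)
    else:
        body = _dec(8.58) * _dec(weight) + _dec(5.09) * _dec(height) \
            - _dec(4.72) * _dec(age) - _dec(74.5)
    ratio = _dec(una) / (_dec(ucrea_mg_dl) * 10)
    return float(23 * _dec(16.3) * _mp.sqrt(ratio * body))


def tanaka_oracle(age, weight, height, una, ucrea_mg_dl) -> float:
    body = -_dec(2.04) * _dec(age) + _dec(14.89) * _dec(weight) \
        + _dec(16.14) * _dec(height) - _dec(2244.45)
    ratio = _dec(una) / (_dec(ucrea_mg_dl) * 10)
    return float(23 * _dec(21.98) * _mp.power(ratio * body, _mp.mpf(392) / 1000))


def intersalt_oracle(sex, age, bmi, una, uk, ucrea_mg_dl) -> float:
    ucrea_mmol_l = _dec(ucrea_mg_dl) * 10 / _dec(113.12)
    if sex == "male":
        mmol = (
            _dec(25.46)
            + _dec(0.46) * _dec(una)
            - _dec(2.75) * ucrea_mmol_l
            - _dec(0.13) * _dec(uk)
            + _dec(4.10) * _dec(bmi)
            + _dec(0.26) * _dec(age)
        )
    else:
        mmol = (
            _dec(5.07)
            + _dec(0.34) * _dec(una)
            - _dec(2.16) * ucrea_mmol_l
            - _dec(0.09) * _dec(uk)
            + _dec(2.39) * _dec(bmi)
            + _dec(2.35) * _dec(age)
            - _dec(0.03) * _dec(age) ** 2
        )
    return float(23 * mmol)


def random_physiological_inputs(rng, n):
    """Random inputs spanning the plausible adult ranges of all predictors."""
    for _ in range(n):
        yield {
            "sex": "male" if rng.random() < 0.5 else "female",
            "age": round(rng.uniform(20, 75), 1),
            "weight": round(rng.uniform(45, 120), 1),
            "height": round(rng.uniform(145, 200), 1),
            "una": round(rng.uniform(10, 300), 1),
            "uk": round(rng.uniform(5, 150), 1),
            "ucrea_mg_dl": round(rng.uniform(20, 300), 1),
        }
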
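"""Voltage-dependent rate functions, defined as expression strings.

Channel kinetics are user-configurable, so rate functions are supplied as
small arithmetic expressions in the variable ``v`` (membrane voltage, mV),
e.g. ``"0.1 * vtrap(-(v + 40.0), 10.0)"``.  The mini-language supports
``+ - * /``, ``exp``, ``log`` and the guarded removable singularity
``vtrap(x, y) = x / (exp(x/y) - 1)``, which is evaluated by its series
expansion near x = 0.  Named parameters (``vt``, ``tau_max``, ...) may appear
in expressions and are bound at compile time.
"""

from __future__ import annotations


import numpy as np

__all__ = ["vtrap", "RateFunction", "compile_rate"]


def vtrap(x, y):
    """x / (exp(x/y) - 1), with the removable singularity at x = 0 guarded.

    For |x/y| < 1e-6 the two-term series y*(1 - x/(2y)) is used, matching the
    limit value y at x = 0.
    """
    x = np.asarray(x, dtype=float)
    z = x / y
    small = np.abs(z) < 1e-6
    safe = np.where(small, 1.0, z)
    with np.errstate(over="ignore"):
        out = np.where(small, y * (1.0 - z / 2.0), x / np.expm1(safe))
    if out.ndim == 0:
        return float(out)
    return out


def _check_expression(expr: str, names: set[str]) -> None:
    import ast

    tree = ast.parse(expr, mode="eval")
    allowed = (
        ast.Expression, ast.BinOp, ast.UnaryOp, ast.Call, ast.Name, ast.Load,
        ast.Constant, ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow,
        ast.USub, ast.UAdd,
    )
    for node in ast.walk(tree):
        if not isinstance(node, allowed):
            raise ValueError(
                f"rate expression {expr!r}: construct {type(node).__name__} not allowed"
            )
        if isinstance(node, ast.Name) and node.id not in names:
            raise ValueError(f"rate expression {expr!r}: unknown name {node.id!r}")
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in ("exp", "log", "vtrap"):
                raise ValueError(f"rate expression {expr!r}: only exp/log/vtrap may be called")


class RateFunction:
    """A compiled rate expression f(v), vectorized over voltage.

    Carries its source expression and parameter bindings so channel
    definitions can be digested and round-tripped through configuration.
    """

    def __init__(self, expr: str, params: dict[str, float] | None = None):
        self.expr = expr
        self.params = dict(params or {})
        names = {"v", "exp", "log", "vtrap"} | set(self.params)
        _check_expression(expr, names)
        self._code = compile(expr, "<rate>", "eval")
        self._ns = {
            "exp": np.exp, "log": np.log, "vtrap": vtrap,
            "__builtins__": {},
            **self.params,
        }

    def __call__(self, v):
        with np.errstate(over="ignore", invalid="ignore"):
            out = eval(self._code, self._ns, {"v": np.asarray(v, dtype=float)})
        return np.asarray(out, dtype=float) + np.zeros_like(np.asarray(v, dtype=float))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RateFunction({self.expr!r}, params={self.params})"

    def digest_key(self) -> tuple:
        return (self.expr, tuple(sorted(self.params.items())))


def compile_rate(spec, params: dict[str, float] | None = None) -> RateFunction:
    """Coerce an expression string, callable or RateFunction into a RateFunction.

    Plain callables are wrapped (useful from Python code); they digest by
    identity, so callable-defined gates never merge across definitions.
    """
    if isinstance(spec, RateFunction):
        return spec
    if callable(spec):
        return _CallableRate(spec, f"<callable {id(spec):#x}>")
    return RateFunction(str(spec), params)


class _CallableRate(RateFunction):
    def __init__(self, fn, label: str):
        self._fn = fn
        self.expr = label
        self.params = {}

    def __call__(self, v):
        return np.asarray(self._fn(np.asarray(v, dtype=float)), dtype=float)

    def digest_key(self) -> tuple:
        return (self.expr, ())


def finite_or_raise(values: np.ndarray, voltages: np.ndarray, what: str) -> None:
    bad = ~np.isfinite(values)
    if np.any(bad):
        v = float(np.asarray(voltages)[bad][0])
        raise ValueError(f"{what} evaluates non-finite at V = {v:g} mV")
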
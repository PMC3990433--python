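"""Safe arithmetic expression handling for update rules.

Rules are plain infix expressions over numbers and named quantities with a
small whitelisted surface: ``+ - * / **``, unary minus, comparisons,
``and``/``or``/``not``, the ternary conditional ``a if cond else b`` and the
functions ``min``, ``max``, ``abs``, ``exp``, ``log``, ``sqrt``.  Anything
else (attribute access, subscripts, lambdas, comprehensions...) is rejected
at parse time, so rule evaluation can never execute arbitrary code.
"""

from __future__ import annotations

import ast
import math

from .errors import ExpressionError

#: Functions callable from rules.  ``exp``/``log``/``sqrt`` are guarded so a
#: wild operand yields ``inf``/``nan`` (detected later) instead of raising.
ALLOWED_FUNCTIONS = ("min", "max", "abs", "exp", "log", "sqrt")

#: Names that rules may not shadow with variables/parameters/drivers.
RESERVED_NAMES = frozenset(ALLOWED_FUNCTIONS)

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.BoolOp,
    ast.Compare,
    ast.IfExp,
    ast.Call,
    ast.Name,
    ast.Constant,
    ast.Load,
    # operators
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.Mod,
    ast.USub,
    ast.UAdd,
    ast.Not,
    ast.And,
    ast.Or,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
    ast.Eq,
    ast.NotEq,
)


def _guarded_exp(x):
    if x > 700.0:
        return math.inf
    return math.exp(x)


def _guarded_log(x):
    if x <= 0.0:
        return math.nan
    return math.log(x)


def _guarded_sqrt(x):
    if x < 0.0:
        return math.nan
    return math.sqrt(x)


#: Evaluation namespace shared by every compiled rule.
EVAL_GLOBALS = {
    "__builtins__": {},
    "min": min,
    "max": max,
    "abs": abs,
    "exp": _guarded_exp,
    "log": _guarded_log,
    "sqrt": _guarded_sqrt,
}


class Expression:
    """A validated, compiled rule expression.

    Parameters
    ----------
    source:
        The expression text.
    context:
        Optional description used in error messages (e.g. the variable name
        the rule belongs to).
    """

    def __init__(self, source: str, context: str = "<expression>"):
        self.source = str(source).strip()
        self.context = context
        try:
            tree = ast.parse(self.source, mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(
                f"{context}: cannot parse expression {self.source!r}: {exc.msg}"
            ) from None
        names = set()
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED_NODES):
                raise ExpressionError(
                    f"{context}: forbidden construct "
                    f"{type(node).__name__} in {self.source!r}"
                )
            if isinstance(node, ast.Call):
                func = node.func
                if not isinstance(func, ast.Name) or func.id not in ALLOWED_FUNCTIONS:
                    shown = func.id if isinstance(func, ast.Name) else "<expr>"
                    raise ExpressionError(
                        f"{context}: call to {shown!r} not allowed; "
                        f"allowed functions: {', '.join(ALLOWED_FUNCTIONS)}"
                    )
                if node.keywords:
                    raise ExpressionError(
                        f"{context}: keyword arguments not allowed in rule calls"
                    )
            if isinstance(node, ast.Name):
                names.add(node.id)
            if isinstance(node, ast.Constant) and not isinstance(
                node.value, (int, float)
            ):
                raise ExpressionError(
                    f"{context}: only numeric literals allowed, "
                    f"got {node.value!r}"
                )
        self.names = frozenset(names - set(ALLOWED_FUNCTIONS))
        for name in self.names:
            if name.startswith("_"):
                raise ExpressionError(
                    f"{context}: identifiers may not start with '_': {name!r}"
                )
        self._code = compile(tree, f"<rule:{context}>", "eval")

    def evaluate(self, namespace: dict) -> float:
        """Evaluate against a name -> value mapping."""
        return float(eval(self._code, EVAL_GLOBALS, namespace))

    def __repr__(self):  # pragma: no cover - debugging nicety
        return f"Expression({self.source!r})"
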
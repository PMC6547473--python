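"""Script-corpus mutation: derive single-edit *ill-typed* variants of a valid
script.

Used to validate rejection completeness: every generated variant contains
exactly one edit (unknown function, unknown keyword argument, wrongly typed
argument, unbound variable, or unknown import version) and must be rejected
by static checking before execution.
"""

from __future__ import annotations

import copy
import random

from . import ast
from .pprint import pprint


def _calls(script: ast.Script) -> list[ast.Call]:
    return [n for n in ast.walk(script) if isinstance(n, ast.Call)]


def _mut_unknown_function(script, rng):
    # renaming `preprocess` would change the block syntax itself, making the
    # edit a parse error rather than a type error — keep the corpus ill-typed
    candidates = [c for c in _calls(script) if c.func != "preprocess"]
    if not candidates:
        return None
    call = rng.choice(candidates)
    call.func = "frobnicate_" + call.func
    return f"unknown function {call.func!r}"


def _mut_unknown_kwarg(script, rng):
    with_kw = [c for c in _calls(script) if c.kwargs]
    if not with_kw:
        return None
    call = rng.choice(with_kw)
    i = rng.randrange(len(call.kwargs))
    _, val = call.kwargs[i]
    call.kwargs[i] = ("bogus_argument", val)
    return f"unknown kwarg on {call.func}"


def _mut_wrong_kwarg_type(script, rng):
    candidates = []
    for c in _calls(script):
        for i, (k, v) in enumerate(c.kwargs):
            if isinstance(v, ast.IntLit):
                candidates.append((c, i, k))
    if not candidates:
        return None
    call, i, k = rng.choice(candidates)
    call.kwargs[i] = (k, ast.StrLit(value="oops"))
    return f"string where Integer expected ({call.func} {k})"


def _mut_wrong_arg_type(script, rng):
    # Feed a String literal to a function that wants a data object.
    candidates = [c for c in _calls(script)
                  if c.func in ("map", "select", "as_reads", "count", "preprocess", "write")
                  and c.args]
    if not candidates:
        return None
    call = rng.choice(candidates)
    call.args[0] = ast.StrLit(value="not_a_dataset")
    return f"String argument to {call.func}"


def _mut_unbound_variable(script, rng):
    uses = [n for n in ast.walk(script)
            if isinstance(n, ast.Var) and n.name != "ARGV"]
    if not uses:
        return None
    var = rng.choice(uses)
    var.name = var.name + "_undefined"
    return f"unbound variable {var.name!r}"


def _mut_bad_import_version(script, rng):
    if not script.imports:
        return None
    imp = rng.choice(script.imports)
    imp.version = "99.9"
    return f"unknown version of module {imp.module!r}"


_MUTATORS = [
    _mut_unknown_function,
    _mut_unknown_kwarg,
    _mut_wrong_kwarg_type,
    _mut_wrong_arg_type,
    _mut_unbound_variable,
    _mut_bad_import_version,
]


def make_illtyped_corpus(script: ast.Script, n: int, seed: int = 0) -> list[tuple[str, str]]:
    """Return ``n`` (description, script text) pairs, each one edit away from
    ``script`` and guaranteed ill-typed by construction."""
    rng = random.Random(seed)
    out = []
    i = 0
    while len(out) < n:
        mut = _MUTATORS[i % len(_MUTATORS)]
        i += 1
        variant = copy.deepcopy(script)
        desc = mut(variant, rng)
        if desc is None:
            continue
        out.append((desc, pprint(variant)))
    return out
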
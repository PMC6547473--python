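"""Static type checking with forward type inference.

The type system is closed: values are short reads, read sets, mapped read
sets, counts tables, strings, integers, booleans or void.  Every expression
in an accepted script is annotated with exactly one type, every variable is
bound before use, and every keyword argument is validated against the
function's signature — all before any data is touched.

Assignment is pass-by-value: ``y = x`` binds an independent value, so later
rebindings of ``y`` can never affect ``x`` (runtime values are immutable and
rebinding is the only mutation in the language, which makes the copy
semantics free).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from ..errors import TypeCheckError
from . import ast
from .ast import TypedScript

SUPPORTED_LANGUAGE_VERSIONS = ("0.9", "1.0")


class NGType(enum.Enum):
    SHORTREAD = "ShortRead"
    SHORTREADSET = "ShortReadSet"
    MAPPEDSHORTREADSET = "MappedShortReadSet"
    COUNTS = "CountsTable"
    STRING = "String"
    INTEGER = "Integer"
    BOOL = "Bool"
    VOID = "Void"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Kwarg:
    type: NGType
    required: bool = False


@dataclass(frozen=True)
class Signature:
    """One positional argument (possibly a union of accepted types) + kwargs."""

    name: str
    arg_types: tuple[NGType, ...]
    ret: NGType
    kwargs: dict[str, Kwarg] = field(default_factory=dict)


_WRITABLE = (NGType.COUNTS, NGType.SHORTREADSET, NGType.MAPPEDSHORTREADSET)

BUILTIN_SIGNATURES = {
    s.name: s
    for s in [
        Signature("preprocess", (NGType.SHORTREADSET,), NGType.SHORTREADSET,
                  {"keep_singles": Kwarg(NGType.BOOL)}),
        Signature("substrim", (NGType.SHORTREAD,), NGType.SHORTREAD,
                  {"min_quality": Kwarg(NGType.INTEGER, required=True)}),
        Signature("endtrim", (NGType.SHORTREAD,), NGType.SHORTREAD,
                  {"min_quality": Kwarg(NGType.INTEGER, required=True),
                   "from_ends": Kwarg(NGType.STRING)}),
        Signature("smoothtrim", (NGType.SHORTREAD,), NGType.SHORTREAD,
                  {"min_quality": Kwarg(NGType.INTEGER, required=True),
                   "window": Kwarg(NGType.INTEGER, required=True)}),
        Signature("len", (NGType.SHORTREAD,), NGType.INTEGER),
        Signature("map", (NGType.SHORTREADSET,), NGType.MAPPEDSHORTREADSET,
                  {"reference": Kwarg(NGType.STRING, required=True),
                   "mapper": Kwarg(NGType.STRING)}),
        Signature("select", (NGType.MAPPEDSHORTREADSET,), NGType.MAPPEDSHORTREADSET,
                  {"min_match_size": Kwarg(NGType.INTEGER),
                   "min_identity_pc": Kwarg(NGType.INTEGER),
                   "action": Kwarg(NGType.STRING),
                   "keep": Kwarg(NGType.STRING)}),
        Signature("as_reads", (NGType.MAPPEDSHORTREADSET,), NGType.SHORTREADSET),
        Signature("count", (NGType.MAPPEDSHORTREADSET,), NGType.COUNTS,
                  {"features": Kwarg(NGType.STRING),
                   "multiple": Kwarg(NGType.STRING),
                   "normalization": Kwarg(NGType.STRING),
                   "min_count": Kwarg(NGType.INTEGER)}),
        Signature("write", _WRITABLE, NGType.VOID,
                  {"ofile": Kwarg(NGType.STRING, required=True)}),
    ]
}


@dataclass(frozen=True)
class ModuleInfo:
    name: str
    versions: tuple[str, ...]
    functions: tuple[str, ...] = ()  # names resolved in BUILTIN/MODULE signature pool
    references: tuple[str, ...] = ()  # reference-registry keys the module contributes
    citation: str | None = None

_MOCAT_SIG = Signature("load_mocat_sample", (NGType.STRING,), NGType.SHORTREADSET)

MODULE_SIGNATURES = {"load_mocat_sample": _MOCAT_SIG}

KNOWN_MODULES = {
    m.name: m
    for m in [
        ModuleInfo("mocat", ("0.9", "1.0"), functions=("load_mocat_sample",)),
        ModuleInfo("igc", ("1.0",), references=("igc",),
                   citation="Li J et al. An integrated catalog of reference genes in the "
                            "human gut microbiome. Nat Biotechnol 32, 834-841 (2014)."),
        ModuleInfo("om-rgc", ("1.0",), references=("om-rgc",),
                   citation="Sunagawa S et al. Structure and function of the global ocean "
                            "microbiome. Science 348, 1261359 (2015)."),
        ModuleInfo("mouse-gut", ("1.0",), references=("mouse-gut",),
                   citation="Xiao L et al. A catalog of the mouse gut metagenome. "
                            "Nat Biotechnol 33, 1103-1108 (2015)."),
        ModuleInfo("pig-gut", ("1.0",), references=("pig-gut",),
                   citation="Xiao L et al. A reference gene catalogue of the pig gut "
                            "microbiome. Nat Microbiol 1, 16161 (2016)."),
        ModuleInfo("dog-gut", ("1.0",), references=("dog-gut",),
                   citation="Coelho LP et al. Similarity of the dog and human gut "
                            "microbiomes in gene content and response to diet. "
                            "Microbiome 6, 72 (2018)."),
    ]
}

# Deprecated alias accepted only under language version 0.9.
_DEPRECATED_ALIASES_09 = {"load_sample": "load_mocat_sample"}


class FunctionRegistry:
    """Resolved signature pool for one script: builtins + imported modules."""

    def __init__(self, language_version: str, imports):
        self.language_version = language_version
        self.signatures = dict(BUILTIN_SIGNATURES)
        self.aliases: dict[str, str] = {}
        self.modules: list[ModuleInfo] = []
        for imp in imports:
            mod = KNOWN_MODULES.get(imp.module)
            if mod is None or imp.version not in mod.versions:
                continue  # reported by the checker
            self.modules.append(mod)
            for fname in mod.functions:
                self.signatures[fname] = MODULE_SIGNATURES[fname]
        if language_version == "0.9":
            for alias, target in _DEPRECATED_ALIASES_09.items():
                if target in MODULE_SIGNATURES or target in BUILTIN_SIGNATURES:
                    self.aliases[alias] = target

    def resolve(self, name: str) -> tuple[str, Signature] | None:
        name = self.aliases.get(name, name)
        sig = self.signatures.get(name)
        return None if sig is None else (name, sig)


class _Checker:
    def __init__(self, script: ast.Script):
        self.script = script
        self.findings: list[tuple[str, int, int]] = []
        self.registry = FunctionRegistry(script.language_version, script.imports)

    def error(self, msg: str, node: ast.Node):
        self.findings.append((msg, node.line, node.col))

    def run(self) -> TypedScript:
        s = self.script
        if s.language_version not in SUPPORTED_LANGUAGE_VERSIONS:
            self.error(
                f"unsupported language version {s.language_version!r} "
                f"(supported: {', '.join(SUPPORTED_LANGUAGE_VERSIONS)})", s)
        for imp in s.imports:
            mod = KNOWN_MODULES.get(imp.module)
            if mod is None:
                self.error(f"unknown module {imp.module!r}", imp)
            elif imp.version not in mod.versions:
                self.error(
                    f"unknown version {imp.version!r} of module {imp.module!r} "
                    f"(available: {', '.join(mod.versions)})", imp)
        env: dict[str, NGType] = {}
        for stmt in s.statements:
            self.check_statement(stmt, env)
        if self.findings:
            raise TypeCheckError(self.findings)
        return TypedScript(s, self.registry)

    # --- statements -------------------------------------------------------

    def check_statement(self, stmt: ast.Node, env: dict) -> None:
        if isinstance(stmt, ast.Assign):
            if isinstance(stmt.value, ast.PreprocessBlock):
                env[stmt.target] = self.check_preprocess_block(stmt.value, env)
            else:
                env[stmt.target] = self.infer(stmt.value, env)
            return
        if isinstance(stmt, ast.ExprStatement):
            self.infer(stmt.expr, env)
            return
        raise TypeError(f"unexpected statement node {stmt!r}")  # pragma: no cover

    def check_preprocess_block(self, blk: ast.PreprocessBlock, env: dict) -> NGType:
        call = blk.call
        if len(call.args) != 1:
            self.error("preprocess takes exactly one argument", call)
        else:
            t = self.infer(call.args[0], env)
            if t not in (NGType.SHORTREADSET, None):
                self.error(f"preprocess expects a ShortReadSet, got {t}", call.args[0])
        self.check_kwargs(call, BUILTIN_SIGNATURES["preprocess"], env)
        # block scope: only the read variable is visible
        block_env = {blk.var: NGType.SHORTREAD}
        for st in blk.body:
            self.check_block_statement(st, block_env, blk.var)
        call.ngtype = NGType.SHORTREADSET
        return NGType.SHORTREADSET

    def check_block_statement(self, stmt: ast.Node, env: dict, read_var: str) -> None:
        if isinstance(stmt, (ast.Discard, ast.Continue)):
            return
        if isinstance(stmt, ast.If):
            t = self.infer(stmt.cond, env)
            if t not in (NGType.BOOL, None):
                self.error(f"if condition must be Bool, got {t}", stmt.cond)
            for st in stmt.body:
                self.check_block_statement(st, env, read_var)
            return
        if isinstance(stmt, ast.Assign):
            t = self.infer(stmt.value, env)
            if stmt.target == read_var and t not in (NGType.SHORTREAD, None):
                self.error(
                    f"block variable '{read_var}' must stay a ShortRead, got {t}", stmt)
            env[stmt.target] = t
            return
        raise TypeError(f"unexpected block statement {stmt!r}")  # pragma: no cover

    # --- expressions ------------------------------------------------------

    def infer(self, expr: ast.Node, env: dict) -> NGType | None:
        t = self._infer(expr, env)
        expr.ngtype = t
        return t

    def _infer(self, expr: ast.Node, env: dict) -> NGType | None:
        if isinstance(expr, ast.StrLit):
            return NGType.STRING
        if isinstance(expr, ast.IntLit):
            return NGType.INTEGER
        if isinstance(expr, ast.BoolLit):
            return NGType.BOOL
        if isinstance(expr, ast.Var):
            if expr.name == "ARGV":
                self.error("ARGV may only be used with an index (e.g. ARGV[1])", expr)
                return None
            if expr.name not in env:
                self.error(f"unbound variable {expr.name!r}", expr)
                return None
            return env[expr.name]
        if isinstance(expr, ast.Index):
            if not (isinstance(expr.base, ast.Var) and expr.base.name == "ARGV"):
                self.error("only ARGV supports indexing", expr)
                return None
            it = self.infer(expr.index, env)
            if it not in (NGType.INTEGER, None):
                self.error(f"ARGV index must be an Integer, got {it}", expr.index)
            expr.base.ngtype = None
            return NGType.STRING
        if isinstance(expr, ast.BinOp):
            lt = self.infer(expr.left, env)
            rt = self.infer(expr.right, env)
            if expr.op == "+":
                if lt == rt == NGType.STRING:
                    return NGType.STRING
                if lt == rt == NGType.INTEGER:
                    return NGType.INTEGER
                if None not in (lt, rt):
                    self.error(f"'+' is not defined for {lt} and {rt}", expr)
                return None
            if expr.op in ("==", "!="):
                if None not in (lt, rt) and lt != rt:
                    self.error(f"cannot compare {lt} with {rt}", expr)
                return NGType.BOOL
            # ordering comparisons
            for side, t in ((expr.left, lt), (expr.right, rt)):
                if t not in (NGType.INTEGER, None):
                    self.error(f"ordering comparison requires Integers, got {t}", side)
            return NGType.BOOL
        if isinstance(expr, ast.Call):
            return self.check_call(expr, env)
        raise TypeError(f"unexpected expression node {expr!r}")  # pragma: no cover

    def check_call(self, call: ast.Call, env: dict) -> NGType | None:
        resolved = self.registry.resolve(call.func)
        if resolved is None:
            self.error(f"unknown function {call.func!r}", call)
            for a in call.args:
                self.infer(a, env)
            for _, v in call.kwargs:
                self.infer(v, env)
            return None
        name, sig = resolved
        call.resolved_name = name
        if len(call.args) != 1:
            self.error(f"{name} takes exactly one positional argument, got {len(call.args)}",
                       call)
            for a in call.args:
                self.infer(a, env)
        else:
            t = self.infer(call.args[0], env)
            if t is not None and t not in sig.arg_types:
                expected = " or ".join(str(x) for x in sig.arg_types)
                self.error(f"{name} expects {expected}, got {t}", call.args[0])
        self.check_kwargs(call, sig, env)
        return sig.ret

    def check_kwargs(self, call: ast.Call, sig: Signature, env: dict) -> None:
        seen = set()
        for kname, kexpr in call.kwargs:
            t = self.infer(kexpr, env)
            spec = sig.kwargs.get(kname)
            if spec is None:
                allowed = ", ".join(sorted(sig.kwargs)) or "none"
                self.error(f"unknown keyword argument {kname!r} for {sig.name} "
                           f"(allowed: {allowed})", kexpr)
                continue
            if kname in seen:
                self.error(f"duplicate keyword argument {kname!r}", kexpr)
            seen.add(kname)
            if t is not None and t != spec.type:
                self.error(f"keyword argument {kname!r} of {sig.name} must be "
                           f"{spec.type}, got {t}", kexpr)
        for kname, spec in sig.kwargs.items():
            if spec.required and kname not in seen:
                self.error(f"missing required keyword argument {kname!r} for {sig.name}", call)


def check_types(script: ast.Script) -> TypedScript:
    """Statically check ``script``; returns a TypedScript or raises
    :class:`~ngl.errors.TypeCheckError` carrying *all* findings."""
    return _Checker(script).run()
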
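"""Script execution: pre-flight validation, stage dispatch, run reporting.

Two guarantees shape this module.  First, *all* input/output problems are
found before any data is processed: :func:`preflight_check` probes every
literal input path, output target and reference name the script mentions and
returns the complete list of findings.  Second, results depend only on the
script and its inputs: the runtime configuration (thread count, temp
directory, seed) may change how results are computed, never what they are —
outputs are byte-identical across runs and across configurations, and the
serialized run report deliberately omits wall-clock times for the same
reason.
"""

from __future__ import annotations

import json
import shutil
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import counting, filtering, mapping, preprocess, seqio
from .errors import NGLError, StageError
from .lang import ast
from .lang.ast import TypedScript
from .lang.typecheck import KNOWN_MODULES
from .references import Registry

FRAMEWORK_CITATION = (
    "ngl: a statically typed pipeline language for reproducible gene-catalog "
    "metagenomic profiling (this package)."
)
TOOL_CITATIONS = {
    "bwa": "Li H. Aligning sequence reads, clone sequences and assembly contigs "
           "with BWA-MEM. arXiv:1303.3997 (2013).",
    "minimap2": "Li H. Minimap2: pairwise alignment for nucleotide sequences. "
                "Bioinformatics 34, 3094-3100 (2018).",
}


@dataclass(frozen=True)
class RuntimeConfig:
    """How results are computed; never what they are."""

    threads: int = 1
    temp_dir: Path | None = None
    seed: int = 0
    registry: Registry | None = None
    keep_intermediates: bool = False

    def __post_init__(self):
        if self.threads < 1:
            raise ValueError("threads must be a positive integer")


@dataclass(frozen=True)
class Finding:
    """One pre-flight validation problem."""

    message: str
    line: int | None = None
    col: int | None = None

    def __str__(self) -> str:
        if self.line is None:
            return self.message
        return f"line {self.line}: {self.message}"


@dataclass
class StageRecord:
    name: str
    wall_seconds: float


@dataclass
class RunReport:
    language_version: str = ""
    modules: list = field(default_factory=list)  # (name, version) pairs
    stages: list = field(default_factory=list)  # StageRecord, in-memory only
    outputs: list = field(default_factory=list)
    qc_paths: list = field(default_factory=list)
    citations: list = field(default_factory=list)
    exit_status: int = 0

    def to_json(self) -> str:
        """Deterministic serialization: stage order kept, wall times omitted."""
        return json.dumps(
            {
                "language_version": self.language_version,
                "modules": [{"name": n, "version": v} for n, v in self.modules],
                "stages": [s.name for s in self.stages],
                "outputs": [str(p) for p in self.outputs],
                "qc_reports": [str(p) for p in self.qc_paths],
                "citations": self.citations,
                "exit_status": self.exit_status,
            },
            indent=2,
        ) + "\n"


def collect_citations(module_names, aligners=()) -> list[str]:
    """Ordered, de-duplicated citation list: the framework, then imported
    modules, then each distinct external tool used."""
    out = [FRAMEWORK_CITATION]
    for name in module_names:
        mod = KNOWN_MODULES.get(name)
        if mod is not None and mod.citation and mod.citation not in out:
            out.append(mod.citation)
    for tool in aligners:
        cit = TOOL_CITATIONS.get(tool)
        if cit and cit not in out:
            out.append(cit)
    return out


# --- constant folding over the AST (for pre-flight path discovery) --------


class _NotConst(Exception):
    pass


def _const_eval(expr: ast.Node, cli_args: list[str], env: dict):
    if isinstance(expr, ast.StrLit):
        return expr.value
    if isinstance(expr, ast.IntLit):
        return expr.value
    if isinstance(expr, ast.BoolLit):
        return expr.value
    if isinstance(expr, ast.Index):
        i = _const_eval(expr.index, cli_args, env)
        if not isinstance(i, int) or i < 1 or i > len(cli_args):
            raise _NotConst(f"ARGV[{i}] is not available "
                            f"({len(cli_args)} argument(s) given)")
        return cli_args[i - 1]
    if isinstance(expr, ast.BinOp) and expr.op == "+":
        return _const_eval(expr.left, cli_args, env) + _const_eval(expr.right, cli_args, env)
    if isinstance(expr, ast.Var) and expr.name in env:
        return env[expr.name]
    raise _NotConst("not a constant expression")


def _kwarg_expr(call: ast.Call, name: str) -> ast.Node | None:
    for k, v in call.kwargs:
        if k == name:
            return v
    return None


def preflight_check(script: TypedScript, cli_args: list[str],
                    registry: Registry | None = None) -> list[Finding]:
    """Probe every I/O node of the AST; returns *all* findings (empty list
    means the run may start).  Touches no data beyond stat/access checks."""
    findings: list[Finding] = []
    const_env: dict[str, object] = {}
    args = list(cli_args)

    def resolve(expr: ast.Node):
        try:
            return _const_eval(expr, args, const_env), None
        except _NotConst as e:
            return None, str(e)

    for stmt in script.statements:
        exprs: list[ast.Node] = []
        if isinstance(stmt, ast.Assign):
            if isinstance(stmt.value, ast.PreprocessBlock):
                exprs = [stmt.value.call]
            else:
                exprs = [stmt.value]
        elif isinstance(stmt, ast.ExprStatement):
            exprs = [stmt.expr]
        for node in exprs:
            for call in (n for n in ast.walk(node) if isinstance(n, ast.Call)):
                fname = getattr(call, "resolved_name", call.func)
                if fname == "load_mocat_sample" and call.args:
                    value, err = resolve(call.args[0])
                    if err and "ARGV" in err:
                        findings.append(Finding(err, call.line, call.col))
                    elif value is not None:
                        d = Path(str(value))
                        if not d.is_dir():
                            findings.append(Finding(
                                f"input sample directory does not exist: {d}",
                                call.line, call.col))
                        elif not any(f.endswith(seqio.FASTQ_EXTS)
                                     for f in (p.name for p in d.iterdir())):
                            findings.append(Finding(
                                f"no FASTQ files in sample directory: {d}",
                                call.line, call.col))
                if fname == "map":
                    ref_expr = _kwarg_expr(call, "reference")
                    if ref_expr is not None:
                        value, err = resolve(ref_expr)
                        if value is not None:
                            if registry is None:
                                findings.append(Finding(
                                    f"script maps to reference {value!r} but no "
                                    f"registry was provided", call.line, call.col))
                            else:
                                problem = registry.probe(str(value))
                                if problem:
                                    findings.append(Finding(problem, call.line, call.col))
                if fname == "write":
                    ofile_expr = _kwarg_expr(call, "ofile")
                    if ofile_expr is not None:
                        value, err = resolve(ofile_expr)
                        if err and "ARGV" in err:
                            findings.append(Finding(err, call.line, call.col))
                        elif value is not None:
                            target = Path(str(value))
                            parent = target.parent
                            if not parent.is_dir():
                                findings.append(Finding(
                                    f"output directory does not exist: {parent}",
                                    call.line, call.col))
                            else:
                                import os

                                if not os.access(parent, os.W_OK):
                                    findings.append(Finding(
                                        f"output directory is not writable: {parent}",
                                        call.line, call.col))
        # keep the constant environment up to date for Var references
        if isinstance(stmt, ast.Assign) and not isinstance(stmt.value, ast.PreprocessBlock):
            try:
                const_env[stmt.target] = _const_eval(stmt.value, args, const_env)
            except _NotConst:
                const_env.pop(stmt.target, None)
    return findings


# --- execution ------------------------------------------------------------


class _DiscardSignal(Exception):
    pass


class _ContinueSignal(Exception):
    pass


def _compile_block(blk: ast.PreprocessBlock, interp: "_Interpreter"):
    """Turn a preprocess block into a per-read callable (None = discard)."""

    def eval_expr(expr: ast.Node, env: dict):
        if isinstance(expr, (ast.StrLit, ast.IntLit, ast.BoolLit)):
            return expr.value
        if isinstance(expr, ast.Var):
            return env[expr.name]
        if isinstance(expr, ast.BinOp):
            left = eval_expr(expr.left, env)
            right = eval_expr(expr.right, env)
            return {
                "+": lambda: left + right,
                "<": lambda: left < right,
                "<=": lambda: left <= right,
                ">": lambda: left > right,
                ">=": lambda: left >= right,
                "==": lambda: left == right,
                "!=": lambda: left != right,
            }[expr.op]()
        if isinstance(expr, ast.Call):
            kwargs = {k: eval_expr(v, env) for k, v in expr.kwargs}
            arg = eval_expr(expr.args[0], env)
            fname = getattr(expr, "resolved_name", expr.func)
            if fname == "substrim":
                return preprocess.substrim(arg, kwargs["min_quality"])
            if fname == "endtrim":
                return preprocess.endtrim(arg, kwargs["min_quality"],
                                          kwargs.get("from_ends", "both"))
            if fname == "smoothtrim":
                return preprocess.smoothtrim(arg, kwargs["min_quality"], kwargs["window"])
            if fname == "len":
                return len(arg)
            raise StageError("preprocess", f"function {fname!r} not usable in a block")
        raise StageError("preprocess", f"unsupported expression in block: {expr!r}")

    def run_body(body, env):
        for stmt in body:
            if isinstance(stmt, ast.Discard):
                raise _DiscardSignal()
            if isinstance(stmt, ast.Continue):
                raise _ContinueSignal()
            if isinstance(stmt, ast.If):
                if eval_expr(stmt.cond, env):
                    run_body(stmt.body, env)
            elif isinstance(stmt, ast.Assign):
                env[stmt.target] = eval_expr(stmt.value, env)

    def per_read(read):
        env = {blk.var: read}
        try:
            run_body(blk.body, env)
        except _DiscardSignal:
            return None
        except _ContinueSignal:
            pass
        return env[blk.var]

    return per_read


class _Interpreter:
    def __init__(self, script: TypedScript, config: RuntimeConfig, cli_args: list[str]):
        self.script = script
        self.config = config
        self.cli_args = list(cli_args)
        self.env: dict[str, object] = {}
        self.report = RunReport(
            language_version=script.language_version,
            modules=[(i.module, i.version) for i in script.imports],
        )
        self.aligners_used: list[str] = []
        self.qc_stats: list[preprocess.QCStats] = []
        self._stage_no = 0
        self._owns_tmp = config.temp_dir is None
        self.tmp = Path(config.temp_dir) if config.temp_dir is not None else None

    def run(self) -> RunReport:
        if self.tmp is None:
            self.tmp = Path(tempfile.mkdtemp(prefix="ngl-run-"))
        else:
            self.tmp.mkdir(parents=True, exist_ok=True)
        try:
            for stmt in self.script.statements:
                self.exec_statement(stmt)
            self.write_qc_reports()
        finally:
            if self._owns_tmp and not self.config.keep_intermediates:
                shutil.rmtree(self.tmp, ignore_errors=True)
        self.report.citations = collect_citations(
            (name for name, _ in self.report.modules), self.aligners_used)
        self.report.exit_status = 0
        return self.report

    # --- statements -------------------------------------------------------

    def exec_statement(self, stmt: ast.Node) -> None:
        if isinstance(stmt, ast.Assign):
            if isinstance(stmt.value, ast.PreprocessBlock):
                self.env[stmt.target] = self.exec_preprocess(stmt.value)
            else:
                self.env[stmt.target] = self.eval(stmt.value)
        elif isinstance(stmt, ast.ExprStatement):
            self.eval(stmt.expr)
        else:  # pragma: no cover
            raise StageError("interpreter", f"unexpected statement {stmt!r}")

    def stage_dir(self, name: str) -> Path:
        self._stage_no += 1
        d = self.tmp / f"stage{self._stage_no:02d}_{name}"
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _timed(self, name: str, fn):
        t0 = time.monotonic()
        try:
            result = fn()
        except NGLError:
            raise
        except Exception as e:
            raise StageError(name, str(e)) from e
        self.report.stages.append(StageRecord(name, time.monotonic() - t0))
        return result

    # --- expressions ------------------------------------------------------

    def eval(self, expr: ast.Node):
        if isinstance(expr, (ast.StrLit, ast.IntLit, ast.BoolLit)):
            return expr.value
        if isinstance(expr, ast.Var):
            return self.env[expr.name]
        if isinstance(expr, ast.Index):
            i = self.eval(expr.index)
            if i < 1 or i > len(self.cli_args):
                raise StageError("arguments",
                                 f"ARGV[{i}] is not available "
                                 f"({len(self.cli_args)} argument(s) given)")
            return self.cli_args[i - 1]
        if isinstance(expr, ast.BinOp):
            left, right = self.eval(expr.left), self.eval(expr.right)
            ops = {"+": lambda: left + right, "<": lambda: left < right,
                   "<=": lambda: left <= right, ">": lambda: left > right,
                   ">=": lambda: left >= right, "==": lambda: left == right,
                   "!=": lambda: left != right}
            return ops[expr.op]()
        if isinstance(expr, ast.Call):
            return self.exec_call(expr)
        raise StageError("interpreter", f"unexpected expression {expr!r}")  # pragma: no cover

    def exec_call(self, call: ast.Call):
        fname = getattr(call, "resolved_name", call.func)
        args = [self.eval(a) for a in call.args]
        kwargs = {k: self.eval(v) for k, v in call.kwargs}
        if fname == "load_mocat_sample":
            return self._timed(fname, lambda: seqio.load_mocat_sample(args[0]))
        if fname == "preprocess":  # plain call without a block: identity pass
            return self._timed(fname, lambda: self._preprocess(
                args[0], lambda r: r, kwargs.get("keep_singles", True)))
        if fname == "map":
            return self._timed(fname, lambda: self._map(args[0], kwargs))
        if fname == "select":
            return self._timed(fname, lambda: filtering.select(
                args[0], self.stage_dir("select") / "filtered.sam",
                min_match_size=kwargs.get("min_match_size", 0),
                min_identity=(kwargs["min_identity_pc"] / 100.0
                              if "min_identity_pc" in kwargs else None),
                action=kwargs.get("action", "unmatch"),
                keep=kwargs.get("keep", "all")))
        if fname == "as_reads":
            return self._timed(fname, lambda: filtering.as_reads(
                args[0], self.stage_dir("as_reads")))
        if fname == "count":
            return self._timed(fname, lambda: self._count(args[0], kwargs))
        if fname == "write":
            return self._timed(fname, lambda: self._write(args[0], kwargs["ofile"]))
        raise StageError("interpreter", f"no runtime for function {fname!r}")

    # --- stage implementations -------------------------------------------

    def exec_preprocess(self, blk: ast.PreprocessBlock):
        per_read = _compile_block(blk, self)
        kwargs = {k: self.eval(v) for k, v in blk.call.kwargs}
        reads = self.eval(blk.call.args[0])
        return self._timed("preprocess", lambda: self._preprocess(
            reads, per_read, kwargs.get("keep_singles", True)))

    def _preprocess(self, reads, per_read, keep_singles):
        out, qc = preprocess.preprocess_set(
            reads, per_read, self.stage_dir("preprocess"), keep_singles=keep_singles)
        self.qc_stats.append(qc)
        return out

    def _map(self, reads, kwargs):
        if self.config.registry is None:
            raise StageError("map", "no reference registry configured")
        catalog = self.config.registry.resolve(kwargs["reference"])
        aligner = kwargs.get("mapper", "builtin")
        if aligner in TOOL_CITATIONS:
            self.aligners_used.append(aligner)
        out = self.stage_dir("map") / f"{catalog.name}.sam"
        return mapping.map_reads(reads, catalog, out, aligner=aligner)

    def _count(self, mapped, kwargs):
        catalog = mapped.catalog
        if catalog is None or catalog.annotation_path is None:
            raise StageError("count",
                             "mapped set's reference has no annotation table")
        annotations = counting.AnnotationTable.load(catalog.annotation_path)
        return counting.count(
            mapped, annotations,
            namespace=kwargs.get("features", "OG"),
            policy=kwargs.get("multiple", "dist1"),
            normalization=kwargs.get("normalization", "raw"),
            min_count=kwargs.get("min_count", 0))

    def _write(self, value, ofile: str):
        target = Path(ofile)
        if isinstance(value, counting.CountsTable):
            counting.write_counts(value, target)
        elif isinstance(value, seqio.ShortReadSet):
            seqio.write_fastq(value.iter_reads(), target)
        elif isinstance(value, mapping.MappedShortReadSet):
            shutil.copyfile(value.sam_path, target)
        else:  # pragma: no cover - excluded by the type checker
            raise StageError("write", f"cannot write value of type {type(value).__name__}")
        self.report.outputs.append(target)
        return None

    def write_qc_reports(self) -> None:
        """QC goes to a sibling of the first write target: <target>.qc.tsv."""
        if not self.qc_stats or not self.report.outputs:
            return
        base = Path(self.report.outputs[0])
        for i, qc in enumerate(self.qc_stats):
            suffix = ".qc.tsv" if i == 0 else f".qc{i + 1}.tsv"
            path = base.with_name(base.name + suffix)
            qc.write_tsv(path)
            self.report.qc_paths.append(path)


def run_script(script: TypedScript, config: RuntimeConfig,
               cli_args: list[str]) -> RunReport:
    """Execute a type-checked script (pre-flight must have passed)."""
    return _Interpreter(script, config, cli_args).run()
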
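"""AST node definitions for pipeline scripts.

A parsed :class:`Script` preserves source statement order.  Type checking
annotates expression nodes in place (``ngtype`` attribute) and returns a
:class:`TypedScript` wrapper, so the same node classes serve both phases.

Structural equality (``==``) ignores positions and type annotations, which
is what the parser round-trip law needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(eq=False)
class Node:
    line: int = field(default=0, compare=False)
    col: int = field(default=0, compare=False)

    # positions and inferred types are metadata, not structure
    _META = ("line", "col", "ngtype")

    def __eq__(self, other):
        if type(self) is not type(other):
            return NotImplemented
        for f in fields(self):
            if f.name in self._META:
                continue
            if getattr(self, f.name) != getattr(other, f.name):
                return False
        return True

    def __hash__(self):  # pragma: no cover - nodes are not hashed structurally
        return id(self)


# --- expressions ----------------------------------------------------------


@dataclass(eq=False)
class StrLit(Node):
    value: str = ""


@dataclass(eq=False)
class IntLit(Node):
    value: int = 0


@dataclass(eq=False)
class BoolLit(Node):
    value: bool = False


@dataclass(eq=False)
class Var(Node):
    name: str = ""


@dataclass(eq=False)
class Index(Node):
    """Subscript, e.g. ``ARGV[1]`` (1-based: ARGV[1] is the first argument)."""

    base: Node = None
    index: Node = None


@dataclass(eq=False)
class BinOp(Node):
    op: str = ""
    left: Node = None
    right: Node = None


@dataclass(eq=False)
class Call(Node):
    func: str = ""
    args: list = field(default_factory=list)
    kwargs: list = field(default_factory=list)  # list of (name, expr) in source order


# --- statements -----------------------------------------------------------


@dataclass(eq=False)
class Assign(Node):
    target: str = ""
    value: Node = None


@dataclass(eq=False)
class ExprStatement(Node):
    expr: Node = None


@dataclass(eq=False)
class Discard(Node):
    pass


@dataclass(eq=False)
class Continue(Node):
    pass


@dataclass(eq=False)
class If(Node):
    cond: Node = None
    body: list = field(default_factory=list)


@dataclass(eq=False)
class PreprocessBlock(Node):
    """``x = preprocess(input, ...) using |read|:`` with an indented body.

    ``call`` is the preprocess Call node (input expression + kwargs);
    ``var`` the block-local read variable.
    """

    call: Call = None
    var: str = ""
    body: list = field(default_factory=list)


@dataclass(eq=False)
class Import(Node):
    module: str = ""
    version: str = ""


@dataclass(eq=False)
class Script(Node):
    language_version: str = ""
    imports: list = field(default_factory=list)
    statements: list = field(default_factory=list)


class TypedScript:
    """A Script that passed static checking; expressions carry ``ngtype``."""

    def __init__(self, script: Script, registry):
        self.script = script
        self.registry = registry

    @property
    def language_version(self):
        return self.script.language_version

    @property
    def imports(self):
        return self.script.imports

    @property
    def statements(self):
        return self.script.statements


def walk(node):
    """Yield ``node`` and every descendant AST node (pre-order)."""
    if isinstance(node, Node):
        yield node
        for f in fields(node):
            yield from walk(getattr(node, f.name))
    elif isinstance(node, list):
        for item in node:
            yield from walk(item)
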
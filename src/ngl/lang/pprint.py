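"""Canonical pretty-printer: ``parse(pprint(parse(s)))`` is structurally
identical to ``parse(s)`` for every valid script."""

from __future__ import annotations

from . import ast

_INDENT = "    "


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def pprint_expr(node: ast.Node) -> str:
    if isinstance(node, ast.StrLit):
        return f'"{_escape(node.value)}"'
    if isinstance(node, ast.IntLit):
        return str(node.value)
    if isinstance(node, ast.BoolLit):
        return "true" if node.value else "false"
    if isinstance(node, ast.Var):
        return node.name
    if isinstance(node, ast.Index):
        return f"{pprint_expr(node.base)}[{pprint_expr(node.index)}]"
    if isinstance(node, ast.BinOp):
        return f"{pprint_expr(node.left)} {node.op} {pprint_expr(node.right)}"
    if isinstance(node, ast.Call):
        parts = [pprint_expr(a) for a in node.args]
        parts += [f"{k}={pprint_expr(v)}" for k, v in node.kwargs]
        return f"{node.func}({', '.join(parts)})"
    raise TypeError(f"not an expression node: {node!r}")


def _pprint_stmt(node: ast.Node, depth: int, out: list[str]) -> None:
    pad = _INDENT * depth
    if isinstance(node, ast.Assign):
        if isinstance(node.value, ast.PreprocessBlock):
            blk = node.value
            out.append(f"{pad}{node.target} = {pprint_expr(blk.call)} using |{blk.var}|:")
            for s in blk.body:
                _pprint_stmt(s, depth + 1, out)
        else:
            out.append(f"{pad}{node.target} = {pprint_expr(node.value)}")
        return
    if isinstance(node, ast.ExprStatement):
        out.append(f"{pad}{pprint_expr(node.expr)}")
        return
    if isinstance(node, ast.If):
        out.append(f"{pad}if {pprint_expr(node.cond)}:")
        for s in node.body:
            _pprint_stmt(s, depth + 1, out)
        return
    if isinstance(node, ast.Discard):
        out.append(f"{pad}discard")
        return
    if isinstance(node, ast.Continue):
        out.append(f"{pad}continue")
        return
    raise TypeError(f"not a statement node: {node!r}")


def pprint(script: ast.Script) -> str:
    """Render a Script in canonical formatting."""
    out = [f'ngless "{_escape(script.language_version)}"']
    if script.imports:
        out.append("")
        for imp in script.imports:
            out.append(f'import "{_escape(imp.module)}" version "{_escape(imp.version)}"')
    out.append("")
    for stmt in script.statements:
        _pprint_stmt(stmt, 0, out)
    return "\n".join(out) + "\n"
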
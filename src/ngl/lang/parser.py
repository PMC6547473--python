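"""Recursive-descent parser producing a :class:`~ngl.lang.ast.Script`.

Grammar (statement subset)::

    script      := version_decl { import_decl } { statement }
    version_decl:= "ngless" STR NEWLINE
    import_decl := "import" STR "version" STR NEWLINE
    statement   := assignment | expr NEWLINE
    assignment  := ID "=" (preprocess | expr) NEWLINE
    preprocess  := call "using" "|" ID "|" ":" NEWLINE INDENT block DEDENT
    block_stmt  := assignment | if_stmt | "discard" NEWLINE | "continue" NEWLINE
    if_stmt     := "if" expr ":" (simple NEWLINE | NEWLINE INDENT block DEDENT)
    expr        := additive [ cmp_op additive ]
    additive    := atom { "+" atom }
    atom        := STR | INT | "true" | "false" | call | ID [ "[" expr "]" ]
                 | "(" expr ")"
    call        := ID "(" [ expr {"," expr} ] {"," ID "=" expr} ")"
"""

from __future__ import annotations

from ..errors import ParseError
from . import ast
from .tokens import DEDENT, EOF, ID, INDENT, INT, KW, NEWLINE, STR, SYM, Token, tokenize

_CMP_OPS = {"==", "!=", "<", "<=", ">", ">="}


class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.pos = 0

    # --- token helpers ---------------------------------------------------

    def peek(self) -> Token:
        return self.tokens[self.pos]

    def next(self) -> Token:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def at(self, kind: str, value: str | None = None) -> bool:
        tok = self.peek()
        return tok.kind == kind and (value is None or tok.value == value)

    def expect(self, kind: str, value: str | None = None, what: str | None = None) -> Token:
        tok = self.peek()
        if not self.at(kind, value):
            want = what or (value if value is not None else kind.lower())
            raise ParseError(f"expected {want}, found {tok.value or tok.kind!r}", tok.line, tok.col)
        return self.next()

    def skip_newlines(self):
        while self.at(NEWLINE):
            self.next()

    # --- grammar ----------------------------------------------------------

    def parse_script(self) -> ast.Script:
        self.skip_newlines()
        tok = self.peek()
        if not self.at(KW, "ngless"):
            raise ParseError(
                "missing version declaration (script must start with: ngless \"<version>\")",
                tok.line,
                tok.col,
            )
        self.next()
        ver = self.expect(STR, what="language version string")
        script = ast.Script(line=tok.line, col=tok.col, language_version=ver.value)
        self.expect(NEWLINE)
        self.skip_newlines()
        while self.at(KW, "import"):
            itok = self.next()
            mod = self.expect(STR, what="module name string")
            self.expect(KW, "version")
            mver = self.expect(STR, what="module version string")
            self.expect(NEWLINE)
            script.imports.append(
                ast.Import(line=itok.line, col=itok.col, module=mod.value, version=mver.value)
            )
            self.skip_newlines()
        while not self.at(EOF):
            script.statements.append(self.parse_statement())
            self.skip_newlines()
        return script

    def parse_statement(self) -> ast.Node:
        tok = self.peek()
        if tok.kind == ID and self.tokens[self.pos + 1].kind == SYM \
                and self.tokens[self.pos + 1].value == "=":
            return self.parse_assignment(block=False)
        expr = self.parse_expr()
        self.expect(NEWLINE)
        return ast.ExprStatement(line=tok.line, col=tok.col, expr=expr)

    def parse_assignment(self, block: bool) -> ast.Node:
        name = self.expect(ID)
        self.expect(SYM, "=")
        value = self.parse_expr()
        if not block and self.at(KW, "using"):
            if not (isinstance(value, ast.Call) and value.func == "preprocess"):
                tok = self.peek()
                raise ParseError("'using' block is only valid after a preprocess(...) call",
                                 tok.line, tok.col)
            self.next()
            self.expect(SYM, "|")
            var = self.expect(ID, what="block variable name")
            self.expect(SYM, "|")
            self.expect(SYM, ":")
            self.expect(NEWLINE)
            body = self.parse_block()
            node = ast.PreprocessBlock(line=name.line, col=name.col, call=value,
                                       var=var.value, body=body)
            return ast.Assign(line=name.line, col=name.col, target=name.value, value=node)
        self.expect(NEWLINE)
        return ast.Assign(line=name.line, col=name.col, target=name.value, value=value)

    def parse_block(self) -> list:
        self.skip_newlines()
        self.expect(INDENT, what="an indented block")
        body = []
        while not self.at(DEDENT):
            body.append(self.parse_block_statement())
            self.skip_newlines()
        self.next()  # DEDENT
        if not body:  # pragma: no cover - INDENT implies at least one line
            tok = self.peek()
            raise ParseError("empty block", tok.line, tok.col)
        return body

    def parse_block_statement(self) -> ast.Node:
        tok = self.peek()
        if self.at(KW, "discard"):
            self.next()
            self.expect(NEWLINE)
            return ast.Discard(line=tok.line, col=tok.col)
        if self.at(KW, "continue"):
            self.next()
            self.expect(NEWLINE)
            return ast.Continue(line=tok.line, col=tok.col)
        if self.at(KW, "if"):
            self.next()
            cond = self.parse_expr()
            self.expect(SYM, ":")
            if self.at(NEWLINE):
                self.next()
                body = self.parse_block()
            else:
                body = [self.parse_block_statement()]
            return ast.If(line=tok.line, col=tok.col, cond=cond, body=body)
        if tok.kind == ID and self.tokens[self.pos + 1].kind == SYM \
                and self.tokens[self.pos + 1].value == "=":
            return self.parse_assignment(block=True)
        raise ParseError("expected assignment, 'if', 'discard' or 'continue' in block",
                         tok.line, tok.col)

    # --- expressions ------------------------------------------------------

    def parse_expr(self) -> ast.Node:
        left = self.parse_additive()
        if self.at(SYM) and self.peek().value in _CMP_OPS:
            op = self.next()
            right = self.parse_additive()
            return ast.BinOp(line=op.line, col=op.col, op=op.value, left=left, right=right)
        return left

    def parse_additive(self) -> ast.Node:
        left = self.parse_atom()
        while self.at(SYM, "+"):
            op = self.next()
            right = self.parse_atom()
            left = ast.BinOp(line=op.line, col=op.col, op="+", left=left, right=right)
        return left

    def parse_atom(self) -> ast.Node:
        tok = self.peek()
        if tok.kind == STR:
            self.next()
            return ast.StrLit(line=tok.line, col=tok.col, value=tok.value)
        if tok.kind == INT:
            self.next()
            return ast.IntLit(line=tok.line, col=tok.col, value=int(tok.value))
        if self.at(KW, "true") or self.at(KW, "false"):
            self.next()
            return ast.BoolLit(line=tok.line, col=tok.col, value=tok.value == "true")
        if self.at(SYM, "("):
            self.next()
            inner = self.parse_expr()
            self.expect(SYM, ")")
            return inner
        if tok.kind == ID:
            self.next()
            if self.at(SYM, "("):
                return self.parse_call_tail(tok)
            if self.at(SYM, "["):
                self.next()
                idx = self.parse_expr()
                self.expect(SYM, "]")
                return ast.Index(line=tok.line, col=tok.col,
                                 base=ast.Var(line=tok.line, col=tok.col, name=tok.value),
                                 index=idx)
            return ast.Var(line=tok.line, col=tok.col, name=tok.value)
        raise ParseError(f"expected an expression, found {tok.value or tok.kind!r}",
                         tok.line, tok.col)

    def parse_call_tail(self, name: Token) -> ast.Call:
        self.expect(SYM, "(")
        call = ast.Call(line=name.line, col=name.col, func=name.value)
        seen_kw = False
        if not self.at(SYM, ")"):
            while True:
                tok = self.peek()
                if tok.kind == ID and self.tokens[self.pos + 1].kind == SYM \
                        and self.tokens[self.pos + 1].value == "=":
                    self.next()
                    self.next()
                    call.kwargs.append((tok.value, self.parse_expr()))
                    seen_kw = True
                else:
                    if seen_kw:
                        raise ParseError("positional argument after keyword argument",
                                         tok.line, tok.col)
                    call.args.append(self.parse_expr())
                if self.at(SYM, ","):
                    self.next()
                    continue
                break
        self.expect(SYM, ")")
        return call


def parse(source: str) -> ast.Script:
    """Parse script text into a Script AST.

    Raises :class:`~ngl.errors.LexicalError` or :class:`~ngl.errors.ParseError`
    with line/column positions.
    """
    return _Parser(tokenize(source)).parse_script()
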
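"""Boolean networks in the BoolNet text dialect.

A Boolean network over ``d`` genes assigns each gene a logic rule (a Boolean
expression over the gene names and the constants 0/1).  All genes update
synchronously: the state at time ``k`` is obtained by evaluating every rule on
the state at time ``k-1``.  Networks are written in the plain-text
"targets, factors" format popularised by BoolNet, e.g.::

    targets, factors
    A, !B
    B, A & (C | 0)
    C, B

Only deterministic synchronous networks are supported; probabilistic and
temporal rule extensions are rejected, because the hidden-state process of a
partially-observed Boolean dynamical system requires a single deterministic
network function.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BooleanNetwork",
    "BoolNetSyntaxError",
    "StateIndexCodec",
    "AttractorReport",
    "parse_boolnet",
    "load_network",
    "serialize_boolnet",
    "network_step",
    "find_attractors",
]

_MAX_EXACT_GENES = 20  # guard for exhaustive 2^d enumeration


class BoolNetSyntaxError(ValueError):
    """Malformed or unsupported network document (carries a line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Expression grammar:  expr := term ('|' term)* ; term := factor ('&' factor)*
#                      factor := '!' factor | '(' expr ')' | name | 0 | 1
# AST nodes are tuples: ('var', name) ('const', v) ('not', a) ('and', a, b)
# ('or', a, b).  NOT binds tighter than AND, AND tighter than OR.
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_.]*)|(?P<op>[!&|()])|(?P<const>[01])|(?P<bad>\S))")


def _tokenize(text: str, line: int) -> list[tuple[str, str]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or not m.group(0).strip():
            break
        if m.group("bad"):
            raise BoolNetSyntaxError(f"unexpected character {m.group('bad')!r} in rule expression", line)
        for kind in ("name", "op", "const"):
            if m.group(kind):
                tokens.append((kind, m.group(kind)))
        pos = m.end()
    return tokens


class _RuleParser:
    def __init__(self, tokens: list[tuple[str, str]], line: int):
        self.tokens = tokens
        self.i = 0
        self.line = line

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.i != len(self.tokens):
            raise BoolNetSyntaxError(f"trailing input near {self.peek()[1]!r}", self.line)
        return node

    def expr(self):
        node = self.term()
        while self.peek() == ("op", "|"):
            self.take()
            node = ("or", node, self.term())
        return node

    def term(self):
        node = self.factor()
        while self.peek() == ("op", "&"):
            self.take()
            node = ("and", node, self.factor())
        return node

    def factor(self):
        kind, val = self.take()
        if kind == "op" and val == "!":
            return ("not", self.factor())
        if kind == "op" and val == "(":
            node = self.expr()
            if self.take() != ("op", ")"):
                raise BoolNetSyntaxError("unbalanced parentheses", self.line)
            return node
        if kind == "name":
            return ("var", val)
        if kind == "const":
            return ("const", int(val))
        raise BoolNetSyntaxError("empty or truncated rule expression", self.line)


def _eval_ast(node, env: dict[str, np.ndarray]) -> np.ndarray:
    op = node[0]
    if op == "var":
        return env[node[1]]
    if op == "const":
        return np.full_like(next(iter(env.values())), node[1]) if env else np.asarray(node[1], dtype=np.uint8)
    if op == "not":
        return 1 - _eval_ast(node[1], env)
    a = _eval_ast(node[1], env)
    b = _eval_ast(node[2], env)
    if op == "and":
        return a & b
    if op == "or":
        return a | b
    raise AssertionError(f"unknown AST node {op!r}")


def _vars_of(node, acc: set[str]):
    if node[0] == "var":
        acc.add(node[1])
    elif node[0] == "not":
        _vars_of(node[1], acc)
    elif node[0] in ("and", "or"):
        _vars_of(node[1], acc)
        _vars_of(node[2], acc)


_PRECEDENCE = {"or": 0, "and": 1, "not": 2, "var": 3, "const": 3}


def _unparse(node, parent_prec: int = 0) -> str:
    op = node[0]
    prec = _PRECEDENCE[op]
    if op == "var":
        return node[1]
    if op == "const":
        return str(node[1])
    if op == "not":
        return "!" + _unparse(node[1], prec)
    sym = " | " if op == "or" else " & "
    s = sym.join(_unparse(c, prec) for c in node[1:])
    return f"({s})" if prec < parent_prec else s


@dataclass(frozen=True)
class BooleanNetwork:
    """A synchronous deterministic Boolean network.

    Attributes
    ----------
    genes : tuple of str
        Ordered gene names; the state vector follows this order.
    rules : tuple
        One parsed rule expression (AST) per gene, same order as ``genes``.
    """

    genes: tuple[str, ...]
    rules: tuple = field(repr=False)

    def __post_init__(self):
        if len(self.genes) < 1:
            raise ValueError("network must contain at least one gene")
        if len(self.rules) != len(self.genes):
            raise ValueError("exactly one rule per gene is required")

    @property
    def d(self) -> int:
        return len(self.genes)

    def rule_text(self, gene: str) -> str:
        """Rule for ``gene`` rendered back to BoolNet expression syntax."""
        return _unparse(self.rules[self.genes.index(gene)])


@dataclass(frozen=True)
class StateIndexCodec:
    """Bijection between Boolean vectors in ``{0,1}^d`` and ``0..2^d - 1``.

    Gene 1 is the most significant bit: ``index = sum_j x_j * 2^(d-j)``, i.e.
    states enumerate lexicographically in the printed gene order.
    """

    d: int

    @property
    def n_states(self) -> int:
        return 1 << self.d

    def encode(self, x) -> int:
        x = np.asarray(x)
        if x.shape != (self.d,):
            raise ValueError(f"state must have length {self.d}, got shape {x.shape}")
        idx = 0
        for v in x:
            idx = (idx << 1) | int(v)
        return idx

    def decode(self, i: int) -> np.ndarray:
        if not 0 <= i < self.n_states:
            raise ValueError(f"state index {i} out of range [0, {self.n_states})")
        return np.array([(i >> (self.d - 1 - j)) & 1 for j in range(self.d)], dtype=np.int8)

    def all_states(self) -> np.ndarray:
        """(2^d, d) matrix of all states in index order."""
        i = np.arange(self.n_states, dtype=np.int64)
        shifts = np.arange(self.d - 1, -1, -1)
        return ((i[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def parse_boolnet(text: str) -> BooleanNetwork:
    """Parse a BoolNet "targets, factors" document into a :class:`BooleanNetwork`.

    Raises
    ------
    BoolNetSyntaxError
        On malformed syntax, duplicate targets, references to undeclared
        genes, or probabilistic/temporal rule extensions (unsupported here).
    """
    lines = text.splitlines()
    entries: list[tuple[int, str, str]] = []  # (line_no, target, expression)
    header_seen = False
    for no, raw in enumerate(lines, start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if not header_seen:
            fields = [f.strip().lower() for f in stripped.split(",")]
            if fields[:2] != ["targets", "factors"]:
                raise BoolNetSyntaxError('expected header "targets, factors"', no)
            if len(fields) > 2:
                raise BoolNetSyntaxError(
                    "unsupported network class: extra header columns "
                    "(probabilistic/temporal networks are not supported)", no)
            header_seen = True
            continue
        if "," not in stripped:
            raise BoolNetSyntaxError('expected "gene, expression"', no)
        target, rest = stripped.split(",", 1)
        target = target.strip()
        rest = rest.strip()
        if "," in rest:
            tail = rest.rsplit(",", 1)[1].strip()
            try:
                float(tail)
            except ValueError:
                raise BoolNetSyntaxError("unexpected comma in rule expression", no) from None
            raise BoolNetSyntaxError(
                "unsupported network class: probabilistic rule (trailing probability)", no)
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", target):
            raise BoolNetSyntaxError(f"invalid target gene name {target!r}", no)
        entries.append((no, target, rest))
    if not header_seen:
        raise BoolNetSyntaxError('missing "targets, factors" header')
    if not entries:
        raise BoolNetSyntaxError("no rules found after header")

    genes, rules = [], []
    for no, target, expr_text in entries:
        if target in genes:
            raise BoolNetSyntaxError(f"duplicate target gene {target!r}", no)
        tokens = _tokenize(expr_text, no)
        if any(kind == "name" and val.lower() in ("timeis", "timegt", "timelt") for kind, val in tokens):
            raise BoolNetSyntaxError("unsupported network class: temporal predicate", no)
        rules.append(_RuleParser(tokens, no).parse())
        genes.append(target)

    declared = set(genes)
    for (no, target, _), rule in zip(entries, rules):
        used: set[str] = set()
        _vars_of(rule, used)
        unknown = sorted(used - declared)
        if unknown:
            raise BoolNetSyntaxError(
                f"rule for {target!r} references undeclared gene(s): {', '.join(unknown)}", no)
    return BooleanNetwork(genes=tuple(genes), rules=tuple(rules))


def load_network(path) -> BooleanNetwork:
    """Read and parse a BoolNet file from ``path``."""
    with open(path, encoding="utf-8") as fh:
        return parse_boolnet(fh.read())


def serialize_boolnet(net: BooleanNetwork) -> str:
    """Render a network back to BoolNet text (reparses to the same truth table)."""
    lines = ["targets, factors"]
    for gene, rule in zip(net.genes, net.rules):
        lines.append(f"{gene}, {_unparse(rule)}")
    return "\n".join(lines) + "\n"


def network_step(net: BooleanNetwork, x) -> np.ndarray:
    """Apply the synchronous network function f to one state vector."""
    x = np.asarray(x)
    if x.shape != (net.d,):
        raise ValueError(f"state must have length {net.d}, got shape {x.shape}")
    env = {g: np.asarray(int(v), dtype=np.uint8) for g, v in zip(net.genes, x)}
    out = np.empty(net.d, dtype=np.int8)
    for j, rule in enumerate(net.rules):
        out[j] = int(_eval_ast(rule, env)) & 1
    return out


def truth_table(net: BooleanNetwork) -> np.ndarray:
    """(2^d, d) matrix: row i is f(s_i) for state index i (MSB-first codec)."""
    if net.d > _MAX_EXACT_GENES:
        raise ValueError(f"state space 2^{net.d} too large to enumerate (limit d <= {_MAX_EXACT_GENES})")
    states = StateIndexCodec(net.d).all_states().astype(np.uint8)
    env = {g: states[:, j] for j, g in enumerate(net.genes)}
    cols = [np.broadcast_to(_eval_ast(rule, env) & 1, (states.shape[0],)) for rule in net.rules]
    return np.column_stack(cols).astype(np.int8)


def state_map_indices(net: BooleanNetwork) -> np.ndarray:
    """Image of each state index under f, as an index array of length 2^d."""
    tt = truth_table(net).astype(np.int64)
    shifts = np.arange(net.d - 1, -1, -1)
    return (tt << shifts[None, :]).sum(axis=1)


@dataclass(frozen=True)
class AttractorReport:
    """Attractors of the noiseless synchronous dynamics.

    ``fixed_points`` are states with f(s) = s; ``cycles`` are the longer
    terminal cycles, each a sequence of state vectors in visiting order.
    """

    fixed_points: list[np.ndarray]
    cycles: list[list[np.ndarray]]
    basin_sizes: dict[int, int]  # attractor id -> number of states draining to it


def find_attractors(net: BooleanNetwork) -> AttractorReport:
    """Exhaustively find all attractors of the deterministic synchronous map.

    Iterates f from every one of the 2^d states (d <= 20) and collects the
    terminal cycles of the functional graph; length-1 cycles are reported as
    fixed points.
    """
    fmap = state_map_indices(net)
    n = fmap.shape[0]
    codec = StateIndexCodec(net.d)
    label = np.full(n, -1, dtype=np.int64)  # attractor id per state
    cycles_idx: list[list[int]] = []
    for start in range(n):
        if label[start] >= 0:
            continue
        path = []
        seen_at = {}
        s = start
        while label[s] < 0 and s not in seen_at:
            seen_at[s] = len(path)
            path.append(s)
            s = int(fmap[s])
        if label[s] >= 0:
            aid = int(label[s])
        else:  # found a new cycle within this path
            aid = len(cycles_idx)
            cycles_idx.append(path[seen_at[s]:])
        for v in path:
            label[v] = aid
    fixed, cycles = [], []
    basin: dict[int, int] = {}
    counts = np.bincount(label, minlength=len(cycles_idx))
    for aid, cyc in enumerate(cycles_idx):
        basin[aid] = int(counts[aid])
        if len(cyc) == 1:
            fixed.append(codec.decode(cyc[0]))
        else:
            cycles.append([codec.decode(i) for i in cyc])
    return AttractorReport(fixed_points=fixed, cycles=cycles, basin_sizes=basin)
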
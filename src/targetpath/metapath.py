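"""Metapath grammar: parse, format and build metaedge-sequence templates.

A *metapath* is an ordered sequence of metaedge types connecting metanode
types, e.g. ``DI = asw = GE = ppi = GE`` -- disease associated with a gene
that interacts with the target gene.  Concrete paths in the graph
*instantiate* a metapath.

Grammar: node-type tokens alternate with metaedge tokens; both separators
flanking an edge token must match.  ``=`` traverses an undirected metaedge,
``>`` a directed metaedge forward (head to tail), ``<`` backward.  The
grammar is whitespace-insensitive; :func:`format_metapath` emits the
canonical single-spaced form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import GrammarError, MetapathParseError, SchemaError
from .schema import Schema

__all__ = [
    "Metapath",
    "parse_metapath",
    "format_metapath",
    "load_metapaths",
    "save_metapaths",
    "DEFAULT_CATALOGUE_STRINGS",
]

FORWARD = "forward"
BACKWARD = "backward"
UNDIRECTED = "undirected"

_SEP_OF = {UNDIRECTED: "=", FORWARD: ">", BACKWARD: "<"}


@dataclass(frozen=True)
class Metapath:
    """A typed path template.

    ``steps`` is a tuple of ``(metaedge code, orientation)`` pairs;
    ``node_types`` the derived metanode sequence (one longer than steps).
    """

    steps: tuple[tuple[str, str], ...]
    node_types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.steps) < 1:
            raise MetapathParseError("metapath must have at least one step")
        if len(self.node_types) != len(self.steps) + 1:
            raise MetapathParseError("node_types length must be steps + 1")

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def id(self) -> str:
        return format_metapath(self)

    def __str__(self) -> str:
        return self.id

    @classmethod
    def from_steps(cls, schema: Schema, start_type: str,
                   steps: list[tuple[str, str]]) -> "Metapath":
        """Build a metapath from a start metanode and (code, orientation) steps,
        deriving and type-checking the metanode sequence."""
        if not schema.has_metanode(start_type):
            raise SchemaError(f"unknown metanode {start_type!r}")
        types = [start_type]
        for code, orient in steps:
            me = schema.metaedge(code)
            cur = types[-1]
            if orient == FORWARD:
                if not me.directed:
                    raise GrammarError(f"{code} is undirected; forward step invalid")
                if cur != me.head_type:
                    raise GrammarError(f"{code} forward requires {me.head_type}, got {cur}")
                nxt = me.tail_type
            elif orient == BACKWARD:
                if not me.directed:
                    raise GrammarError(f"{code} is undirected; backward step invalid")
                if cur != me.tail_type:
                    raise GrammarError(f"{code} backward requires {me.tail_type}, got {cur}")
                nxt = me.head_type
            elif orient == UNDIRECTED:
                if me.directed:
                    raise GrammarError(f"{code} is directed; use forward/backward")
                if cur == me.head_type:
                    nxt = me.tail_type
                elif cur == me.tail_type:
                    nxt = me.head_type
                else:
                    raise GrammarError(
                        f"{code} joins {me.head_type}-{me.tail_type}, not {cur}"
                    )
            else:
                raise MetapathParseError(f"unknown orientation {orient!r}")
            types.append(nxt)
        return cls(steps=tuple(steps), node_types=tuple(types))


_TOKEN_RE = re.compile(r"[A-Za-z_][A-Za-z_0-9]*|[=<>]|\S")


def parse_metapath(text: str, schema: Schema) -> Metapath:
    """Parse a metapath grammar string against *schema*.

    Raises :class:`MetapathParseError` for malformed strings,
    :class:`SchemaError` for unknown tokens and :class:`GrammarError` for
    type-incompatible sequences.
    """
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        raise MetapathParseError("empty metapath string")
    # expected layout: TYPE (SEP EDGE SEP TYPE)+
    if len(tokens) < 5 or (len(tokens) - 1) % 4 != 0:
        raise MetapathParseError(
            f"malformed metapath {text!r}: expected TYPE (SEP EDGE SEP TYPE)+"
        )
    word_positions = set(range(0, len(tokens), 2))
    for i, tok in enumerate(tokens):
        is_sep = tok in "=<>"
        if (i in word_positions) == is_sep:
            raise MetapathParseError(
                f"malformed metapath {text!r}: unexpected token {tok!r} at position {i}"
            )

    start = tokens[0]
    if not schema.has_metanode(start):
        raise SchemaError(f"unknown metanode token {start!r}")
    steps: list[tuple[str, str]] = []
    types = [start]
    for j in range(0, (len(tokens) - 1) // 4):
        s1, code, s2, nxt = tokens[4 * j + 1: 4 * j + 5]
        if s1 != s2:
            raise MetapathParseError(
                f"mismatched separators {s1!r}/{s2!r} around {code!r}"
            )
        if not schema.has_metaedge(code):
            raise SchemaError(f"unknown metaedge token {code!r}")
        if not schema.has_metanode(nxt):
            raise SchemaError(f"unknown metanode token {nxt!r}")
        me = schema.metaedge(code)
        cur = types[-1]
        if s1 == "=":
            if me.directed:
                raise GrammarError(f"{code} is directed; use '>' or '<'")
            if not ({cur, nxt} <= {me.head_type, me.tail_type}
                    and ((cur, nxt) in ((me.head_type, me.tail_type),
                                        (me.tail_type, me.head_type)))):
                raise GrammarError(
                    f"{code} joins {me.head_type}-{me.tail_type}, not {cur}-{nxt}"
                )
            orient = UNDIRECTED
        elif s1 == ">":
            if not me.directed:
                raise GrammarError(f"{code} is undirected; '>' invalid")
            if (cur, nxt) != (me.head_type, me.tail_type):
                raise GrammarError(
                    f"{code} forward joins {me.head_type}>{me.tail_type}, not {cur}>{nxt}"
                )
            orient = FORWARD
        else:  # '<'
            if not me.directed:
                raise GrammarError(f"{code} is undirected; '<' invalid")
            if (cur, nxt) != (me.tail_type, me.head_type):
                raise GrammarError(
                    f"{code} backward joins {me.tail_type}<{me.head_type}, not {cur}<{nxt}"
                )
            orient = BACKWARD
        steps.append((code, orient))
        types.append(nxt)
    return Metapath(steps=tuple(steps), node_types=tuple(types))


def format_metapath(mp: Metapath) -> str:
    """Canonical single-spaced grammar string; inverse of :func:`parse_metapath`."""
    parts = [mp.node_types[0]]
    for (code, orient), nxt in zip(mp.steps, mp.node_types[1:]):
        sep = _SEP_OF[orient]
        parts += [sep, code, sep, nxt]
    return " ".join(parts)


#: Bundled disease-to-gene metapath catalogue used as the default candidate
#: pool (mix of literature co-mention, expression-change, compound-bridge,
#: pathway-co-membership and interaction templates).
DEFAULT_CATALOGUE_STRINGS: tuple[str, ...] = (
    "DI = mnw = DI = asw = GE",
    "DI = mnw = DI = uri = GE",
    "DI = asw = GE > pdi > GE",
    "DI = asw = GE = ppi = GE",
    "DI = oci = AN = oci = DI = asw = GE",
    "DI = trt = CO = trt = DI = asw = GE",
    "DI = trt = CO = trt = DI = uri = GE",
    "DI = trt = CO = bin = GE = ppi = GE",
    "DI = trt = CO = drb = GE = ppi = GE",
    "DI = trt = CO = urb = GE = ppi = GE",
    "DI = asw = GE = bin = CO = drb = GE",
    "DI = asw = GE = bin = CO = urb = GE",
    "DI = asw = GE = drb = CO = drb = GE",
    "DI = asw = GE = drb = CO = urb = GE",
    "DI = asw = GE = inv = PW = inv = GE",
    "DI = dri = GE = ppi = GE",
    "DI = dri = GE = bin = CO = drb = GE",
    "DI = dri = GE = bin = CO = urb = GE",
    "DI = uri = GE = drb = CO = bin = GE",
    "DI = uri = GE = inv = PW = inv = GE",
)


def load_metapaths(path, schema: Schema) -> list[Metapath]:
    """Read a metapath catalogue file (one grammar string per line, ``#``
    starts a comment)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(parse_metapath(line, schema))
    return out


def save_metapaths(metapaths, path) -> None:
    with open(path, "w") as fh:
        for mp in metapaths:
            fh.write(format_metapath(mp) + "\n")
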
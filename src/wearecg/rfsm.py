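"""Reconfigurable multi-pattern matcher over attribute tuples.

Disease patterns are conjunctions of per-attribute numeric ranges on a
fixed attribute set (X, Y, Z, ... each valued in [0, 65536]).  Matching is
compiled, not interpreted:

1. *Discretization* — the range endpoints of all patterns partition each
   attribute's domain into elementary intervals/points; every elementary
   piece gets a symbol (x1, x2, ...).  Adjacent pieces that no pattern
   range distinguishes are merged, so each pattern range is an exact union
   of symbols.
2. *Regex view* — a pattern becomes one alternation group per attribute,
   e.g. ``(x1)(y2|y3|y4)(z5)``, over fixed-length symbol strings.
3. *DFA* — the pattern set is determinized into a lookup table
   ``(state, symbol) -> state`` whose accepting states carry every pattern
   (and action) matching the consumed tuple.  Matching a tuple is then one
   table walk per attribute.

Adding or removing a pattern regenerates alphabet and table
(:func:`reconfigure`); results for tuples untouched by the edit are
unchanged.  Overlapping patterns all report; no precedence is imposed.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field

from .core import ConfigError, DomainError, FormatError

__all__ = [
    "DOMAIN_MAX",
    "AttributeRange",
    "Pattern",
    "Piece",
    "DiscretizationMap",
    "DfaTable",
    "MatchResult",
    "Matcher",
    "derive_alphabet",
    "discretize",
    "compile_patterns",
    "match",
    "reconfigure",
    "default_disease_patterns",
    "patterns_to_json",
    "patterns_from_json",
    "dfa_to_json",
    "dfa_from_json",
]

DOMAIN_MAX = 65536.0


@dataclass(frozen=True)
class AttributeRange:
    """Constraint of one pattern on one attribute.

    Exactly one of three shapes: a wildcard (matches everything), an exact
    value, or an interval with open/closed ends.  All printed table ranges
    are strict ("0 < X < 3" excludes both ends).
    """

    attribute: str
    low: float | None = None
    high: float | None = None
    low_open: bool = True
    high_open: bool = True
    equality: float | None = None
    wildcard: bool = False

    def __post_init__(self) -> None:
        if self.wildcard:
            if self.equality is not None or self.low is not None or self.high is not None:
                raise ConfigError("wildcard range must not carry bounds")
            return
        if self.equality is not None:
            if self.low is not None or self.high is not None:
                raise ConfigError("equality range must not carry interval bounds")
            if not 0 <= self.equality <= DOMAIN_MAX:
                raise ConfigError(f"equality value {self.equality} outside domain")
            return
        if self.low is None or self.high is None:
            raise ConfigError("interval range needs both low and high")
        if not (0 <= self.low <= self.high <= DOMAIN_MAX):
            raise ConfigError(f"malformed range [{self.low}, {self.high}]")

    def contains(self, value: float) -> bool:
        """Numeric membership test — the brute-force reference semantics."""
        if self.wildcard:
            return 0 <= value <= DOMAIN_MAX
        if self.equality is not None:
            return value == self.equality
        above = value > self.low if self.low_open else value >= self.low
        below = value < self.high if self.high_open else value <= self.high
        return above and below

    def critical_points(self) -> set:
        if self.wildcard:
            return set()
        if self.equality is not None:
            return {self.equality}
        return {self.low, self.high}


@dataclass(frozen=True)
class Pattern:
    """A named pattern: one range per attribute plus the action it triggers."""

    id: str
    ranges: tuple  # one AttributeRange per attribute, fixed order
    action: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", tuple(self.ranges))
        attrs = [r.attribute for r in self.ranges]
        if len(attrs) != len(set(attrs)):
            raise ConfigError(f"pattern {self.id}: duplicate attribute")

    @property
    def attributes(self) -> tuple:
        return tuple(r.attribute for r in self.ranges)

    def range_for(self, attribute: str) -> AttributeRange:
        for r in self.ranges:
            if r.attribute == attribute:
                return r
        raise ConfigError(f"pattern {self.id} has no attribute {attribute!r}")

    def matches(self, values) -> bool:
        """Direct numeric evaluation, independent of the compiled route."""
        return all(r.contains(v) for r, v in zip(self.ranges, values))


@dataclass(frozen=True)
class Piece:
    """One elementary piece of an attribute's partition: an interval with
    explicit end closures; a singleton is ``lo == hi`` with both ends
    closed."""

    lo: float
    hi: float
    lo_closed: bool
    hi_closed: bool
    symbol: str

    def contains(self, value: float) -> bool:
        above = value >= self.lo if self.lo_closed else value > self.lo
        below = value <= self.hi if self.hi_closed else value < self.hi
        return above and below

    def representative(self) -> float:
        if self.lo == self.hi:
            return self.lo
        return (self.lo + self.hi) / 2.0

    def describe(self) -> str:
        lo_b = "[" if self.lo_closed else "("
        hi_b = "]" if self.hi_closed else ")"
        if self.lo == self.hi:
            return f"{{{self.lo:g}}}"
        return f"{lo_b}{self.lo:g}, {self.hi:g}{hi_b}"


@dataclass
class DiscretizationMap:
    """Per-attribute elementary partitions of [0, 65536] with their symbols."""

    attributes: tuple
    pieces: dict  # attribute -> list[Piece], ascending, covering the domain

    def symbols(self, attribute: str) -> list:
        return [p.symbol for p in self.pieces[attribute]]

    def piece_for(self, attribute: str, value: float) -> Piece:
        if not 0 <= value <= DOMAIN_MAX:
            raise DomainError(f"{attribute}={value} outside [0, {DOMAIN_MAX:g}]")
        plist = self.pieces[attribute]
        # pieces are ascending and cover the domain; bisect on lower ends
        lows = [p.lo for p in plist]
        i = min(bisect.bisect_right(lows, value), len(plist)) - 1
        for j in (i, i + 1, i - 1):
            if 0 <= j < len(plist) and plist[j].contains(value):
                return plist[j]
        raise DomainError(f"no piece contains {attribute}={value}")  # pragma: no cover

    def pattern_symbols(self, pattern: Pattern, attribute: str) -> list:
        """Symbols whose pieces lie inside the pattern's range — the
        alternation group of the pattern's regex for this attribute."""
        rng = pattern.range_for(attribute)
        out = []
        for p in self.pieces[attribute]:
            if rng.contains(p.representative()):
                if not (rng.contains(p.lo) if p.lo_closed else True) or not (
                    rng.contains(p.hi) if p.hi_closed else True
                ):
                    raise ConfigError(
                        f"piece {p.describe()} straddles range of {pattern.id}"
                    )
                out.append(p.symbol)
        return out


def derive_alphabet(patterns) -> DiscretizationMap:
    """Partition each attribute's domain by all pattern range endpoints.

    Construction: collect critical points (interval endpoints, equality
    values, the domain bounds), form the fine partition of singletons and
    open gaps, then merge adjacent pieces that every pattern range treats
    identically.  The result is the coarsest interval partition for which
    every pattern range is an exact union of pieces; symbols are assigned
    in ascending order per attribute (``x1``, ``x2``, ...).
    """
    patterns = list(patterns)
    if patterns:
        attrs = patterns[0].attributes
        for p in patterns:
            if p.attributes != attrs:
                raise ConfigError(
                    f"pattern {p.id} attribute order {p.attributes} != {attrs}"
                )
    else:
        attrs = ()

    pieces: dict = {}
    for attr in attrs:
        points = {0.0, DOMAIN_MAX}
        for p in patterns:
            points |= {float(v) for v in p.range_for(attr).critical_points()}
        pts = sorted(points)

        fine: list[tuple] = []  # (lo, hi, lo_closed, hi_closed)
        for i, pt in enumerate(pts):
            fine.append((pt, pt, True, True))
            if i + 1 < len(pts):
                fine.append((pt, pts[i + 1], False, False))

        def signature(piece: tuple) -> tuple:
            lo, hi, _, _ = piece
            rep = lo if lo == hi else (lo + hi) / 2.0
            return tuple(p.range_for(attr).contains(rep) for p in patterns)

        merged: list[list] = []
        for piece in fine:
            if merged and signature(tuple(merged[-1])) == signature(piece):
                merged[-1][1] = piece[1]
                merged[-1][3] = piece[3]
            else:
                merged.append(list(piece))

        prefix = attr.lower()
        pieces[attr] = [
            Piece(lo, hi, lc, hc, f"{prefix}{i + 1}")
            for i, (lo, hi, lc, hc) in enumerate(merged)
        ]
    return DiscretizationMap(attributes=attrs, pieces=pieces)


def discretize(values, dmap: DiscretizationMap) -> tuple:
    """Map an attribute tuple to its symbol string (one symbol per
    attribute, fixed attribute order)."""
    if len(values) != len(dmap.attributes):
        raise DomainError(
            f"expected {len(dmap.attributes)} attribute values, got {len(values)}"
        )
    return tuple(
        dmap.piece_for(attr, v).symbol for attr, v in zip(dmap.attributes, values)
    )


@dataclass
class DfaTable:
    """Deterministic lookup-table automaton over fixed-length symbol strings.

    ``transition`` is total: undefined moves land in the absorbing dead
    state.  Accepting states map to the tuple of (pattern id, action) pairs
    of every pattern whose regex accepts the consumed string.
    """

    states: list
    alphabet: list
    transition: dict  # (state, symbol) -> state
    accepting: dict  # state -> tuple[(pattern_id, action), ...]
    start: int
    dead: int

    def step(self, state: int, symbol: str) -> int:
        return self.transition.get((state, symbol), self.dead)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one tuple: all matching patterns and actions."""

    pattern_ids: tuple
    actions: tuple

    @property
    def matched(self) -> bool:
        return len(self.pattern_ids) > 0


def compile_patterns(patterns, dmap: DiscretizationMap) -> DfaTable:
    """Determinize the pattern set into a lookup table.

    Subset construction specialised to fixed-length strings: a state is the
    set of patterns still viable at a given depth; consuming a symbol of
    the depth's attribute intersects with the patterns whose alternation
    group contains that symbol.
    """
    patterns = list(patterns)
    symbol_sets = {
        (i, attr): frozenset(dmap.pattern_symbols(p, attr))
        for i, p in enumerate(patterns)
        for attr in dmap.attributes
    }

    alphabet = [s for attr in dmap.attributes for s in dmap.symbols(attr)]
    state_ids: dict = {}
    transition: dict = {}
    accepting: dict = {}

    def intern(depth: int, viable: frozenset) -> int:
        key = (depth, viable)
        if key not in state_ids:
            state_ids[key] = len(state_ids)
        return state_ids[key]

    start = intern(0, frozenset(range(len(patterns))))
    frontier = [(0, frozenset(range(len(patterns))))]
    seen = {frontier[0]}
    n_attrs = len(dmap.attributes)
    while frontier:
        depth, viable = frontier.pop()
        sid = state_ids[(depth, viable)]
        if depth == n_attrs:
            if viable:
                accepting[sid] = tuple(
                    (patterns[i].id, patterns[i].action) for i in sorted(viable)
                )
            continue
        attr = dmap.attributes[depth]
        for sym in dmap.symbols(attr):
            nxt = frozenset(i for i in viable if sym in symbol_sets[(i, attr)])
            tid = intern(depth + 1, nxt)
            transition[(sid, sym)] = tid
            if (depth + 1, nxt) not in seen:
                seen.add((depth + 1, nxt))
                frontier.append((depth + 1, nxt))

    dead = len(state_ids)  # absorbing sink for out-of-place symbols
    states = list(range(len(state_ids))) + [dead]
    for sid in states:
        for sym in alphabet:
            transition.setdefault((sid, sym), dead)
    return DfaTable(
        states=states,
        alphabet=alphabet,
        transition=transition,
        accepting=accepting,
        start=start,
        dead=dead,
    )


def match(dfa: DfaTable, values, dmap: DiscretizationMap) -> MatchResult:
    """Match one attribute tuple: discretize, walk the table, read labels.

    An empty result means no pattern fired — the tuple is "normal".
    """
    state = dfa.start
    for sym in discretize(values, dmap):
        state = dfa.step(state, sym)
    labels = dfa.accepting.get(state, ())
    return MatchResult(
        pattern_ids=tuple(pid for pid, _ in labels),
        actions=tuple(action for _, action in labels),
    )


@dataclass
class Matcher:
    """Convenience bundle of a pattern set with its compiled artifacts."""

    patterns: list
    dmap: DiscretizationMap = field(init=False)
    dfa: DfaTable = field(init=False)

    def __post_init__(self) -> None:
        self.patterns = list(self.patterns)
        self.dmap = derive_alphabet(self.patterns)
        self.dfa = compile_patterns(self.patterns, self.dmap)

    def match(self, values) -> MatchResult:
        return match(self.dfa, values, self.dmap)


def reconfigure(patterns, add=None, remove_ids=None) -> Matcher:
    """Edit the pattern set and rebuild alphabet + lookup table from scratch.

    Matching results for tuples unaffected by the edit are unchanged (the
    compiled route is a pure function of the pattern set).
    """
    new = list(patterns)
    if remove_ids:
        remove = set(remove_ids)
        new = [p for p in new if p.id not in remove]
    if add is not None:
        new.extend(add if isinstance(add, (list, tuple)) else [add])
    return Matcher(new)


def _interval(attr, lo, hi) -> AttributeRange:
    return AttributeRange(attribute=attr, low=float(lo), high=float(hi))


def default_disease_patterns() -> list:
    """The illustrative seven-pattern set over attributes (X, Y, Z).

    All interval bounds are strict; actions label disease symptoms, an
    artifact marker, and an alarm.  Purely demonstrative — the attribute
    semantics are whatever the deployment maps onto X/Y/Z.
    """
    W = AttributeRange  # noqa: N806 - local alias for brevity
    return [
        Pattern("P1", ( _interval("X", 0, 3), _interval("Y", 2, 10), _interval("Z", 5, 65535)), "Disease 1"),
        Pattern("P2", ( _interval("X", 3, 65535), _interval("Y", 11, 65535), W("Z", equality=2.0)), "Disease 2"),
        Pattern("P3", ( _interval("X", 3, 65535), _interval("Y", 11, 65535), _interval("Z", 0, 3)), "Disease 3"),
        Pattern("P4", ( _interval("X", 4, 65535), W("Y", wildcard=True), _interval("Z", 0, 2)), "Disease 4"),
        Pattern("P5", ( W("X", equality=7.0), W("Y", wildcard=True), W("Z", wildcard=True)), "Artifact"),
        Pattern("P6", ( _interval("X", 10, 65535), _interval("Y", 7, 65535), W("Z", wildcard=True)), "Alarm"),
        Pattern("P7", ( W("X", wildcard=True), _interval("Y", 9, 27), _interval("Z", 0, 2)), "Disease 4"),
    ]


# --------------------------------------------------------------------------
# JSON round-trips (pattern tables and the downloadable lookup table)
# --------------------------------------------------------------------------

def _range_to_obj(r: AttributeRange) -> dict:
    if r.wildcard:
        return {"attribute": r.attribute, "wildcard": True}
    if r.equality is not None:
        return {"attribute": r.attribute, "equality": r.equality}
    return {
        "attribute": r.attribute,
        "low": r.low,
        "high": r.high,
        "low_open": r.low_open,
        "high_open": r.high_open,
    }


def _range_from_obj(obj: dict) -> AttributeRange:
    if obj.get("wildcard"):
        return AttributeRange(attribute=obj["attribute"], wildcard=True)
    if "equality" in obj:
        return AttributeRange(attribute=obj["attribute"], equality=float(obj["equality"]))
    return AttributeRange(
        attribute=obj["attribute"],
        low=float(obj["low"]),
        high=float(obj["high"]),
        low_open=bool(obj.get("low_open", True)),
        high_open=bool(obj.get("high_open", True)),
    )


def patterns_to_json(patterns) -> str:
    return json.dumps(
        [
            {"id": p.id, "action": p.action, "ranges": [_range_to_obj(r) for r in p.ranges]}
            for p in patterns
        ],
        indent=2,
    )


def patterns_from_json(text: str) -> list:
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid pattern JSON: {exc}") from exc
    return [
        Pattern(
            id=obj["id"],
            ranges=tuple(_range_from_obj(r) for r in obj["ranges"]),
            action=obj["action"],
        )
        for obj in raw
    ]


def dfa_to_json(dfa: DfaTable) -> str:
    """Flat lookup-table export — the analogue of a downloadable flash image."""
    return json.dumps(
        {
            "states": dfa.states,
            "alphabet": dfa.alphabet,
            "start": dfa.start,
            "dead": dfa.dead,
            "transition": [[s, sym, t] for (s, sym), t in sorted(dfa.transition.items())],
            "accepting": {str(s): list(map(list, labels)) for s, labels in dfa.accepting.items()},
        }
    )


def dfa_from_json(text: str) -> DfaTable:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid DFA JSON: {exc}") from exc
    return DfaTable(
        states=list(obj["states"]),
        alphabet=list(obj["alphabet"]),
        transition={(s, sym): t for s, sym, t in obj["transition"]},
        accepting={int(s): tuple(tuple(x) for x in labels) for s, labels in obj["accepting"].items()},
        start=obj["start"],
        dead=obj["dead"],
    )

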
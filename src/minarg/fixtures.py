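"""Deterministic worked-example ARGs and random small instances.

``fig2_fixture`` realizes the canonical removal example: a K=3, M=3 ARG
with a marked vertex ``v`` carrying two red and one green outgoing strand,
one red ({c}) and one green ({q}) incoming strand, and the blue tree routed
around ``v``; removing ``v`` produces a red strand labeled {c, d} and a
green strand labeled {q}, and ``v`` is resolvable.

``unbounded_pattern_fixture`` truncates an unbounded K=2, M=2 ARG built
from a repeating cross motif of coalescent-and-exchange vertices, none of
which is t-coalescent: its minimal descriptor is the same bounded graph
(5 vertices, GMRCA degree 2) at every repetition depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arg_model import Arg, ArgError, Strand, is_t_coalescent
from .simulator import SimConfig, annotate_mutations, simulate_binary_arg


def _s(parent, child, tree, labels=()):
    return Strand(parent, child, tree, frozenset(labels))


def fig2_fixture() -> Arg:
    """The removal worked example; the marked vertex is named ``"v"``.

    Trees are numbered red=1, green=2, blue=3 in chromosomal order.
    """
    vertices = {
        "u1": 0.0, "u2": 0.0, "u3": 0.0,
        "v": 2.0,
        "b": 3.0,   # green root
        "w": 3.0,   # blue root
        "a": 4.0,   # red root
    }
    strands = (
        # red tree: ((u1, u2) at v, u3) at a
        _s("a", "v", 1, {"c"}),
        _s("a", "u3", 1),
        _s("v", "u1", 1, {"d"}),
        _s("v", "u2", 1),
        # green tree: (u2 via v, u1, u3) at b
        _s("b", "v", 2, {"q"}),
        _s("b", "u1", 2),
        _s("b", "u3", 2),
        _s("v", "u2", 2),
        # blue tree routed around v
        _s("w", "u1", 3),
        _s("w", "u2", 3),
        _s("w", "u3", 3),
    )
    return Arg(3, (1.0, 1.0, 1.0), vertices, strands, ("u1", "u2", "u3"))


def unbounded_pattern_fixture(depth: int) -> Arg:
    """Finite truncation of an unbounded ARG (K=2, M=2) repeating the
    motif ``depth`` times above the samples.

    Level ``k`` holds two vertices ``v_k`` (children: red below-left, blue
    below-right) and ``w_k`` (the cross), each both coalescent and
    genetic-exchange but not t-coalescent.  There is no GMRCA; removing
    the motif vertices leaves only chain material above the two marginal
    LCAs, so compactification yields the same bounded minimal descriptor
    at every depth.
    """
    if depth < 1:
        raise ArgError(f"depth {depth} < 1")
    vertices = {"u1": 0.0, "u2": 0.0, "R": 1.0, "B": 2.0}
    strands = [
        _s("R", "u1", 1, {"a"}),
        _s("R", "u2", 1),
        _s("B", "u1", 2),
        _s("B", "u2", 2, {"b"}),
    ]
    red_below, blue_below = "R", "B"
    for k in range(1, depth + 1):
        v, w = f"v{k}", f"w{k}"
        vertices[v] = 2.0 * k + 1.0
        vertices[w] = 2.0 * k + 2.0
        strands += [
            _s(v, red_below, 1, {"c"} if k == 1 else ()),
            _s(v, blue_below, 2),
            _s(w, blue_below, 1),  # stale strands: label-free by construction
            _s(w, red_below, 2),
        ]
        red_below, blue_below = v, w
    return Arg(2, (1.0, 1.0), vertices, tuple(strands), ("u1", "u2"))


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request; the same spec always yields the same ARG."""

    name: str  # "fig2" | "unbounded" | "random"
    depth: int = 1
    seed: int = 0
    K: int = 3
    M: int = 2
    max_vertices: int = 12


def build(spec: FixtureSpec) -> Arg:
    if spec.name == "fig2":
        return fig2_fixture()
    if spec.name == "unbounded":
        return unbounded_pattern_fixture(spec.depth)
    if spec.name == "random":
        return random_small_arg(
            K=spec.K, M=spec.M, max_vertices=spec.max_vertices, seed=spec.seed
        )
    raise ArgError(f"unknown fixture {spec.name!r}")


def random_small_arg(
    K: int = 3,
    M: int = 2,
    max_vertices: int = 12,
    seed: int = 0,
    require_non_t_coalescent: bool = False,
    mutation_rate: float = 0.15,
    recomb: float = 0.08,
    N: float = 5.0,
) -> Arg:
    """A small random valid ARG for exhaustive brute-force testing.

    Rejection-samples the coalescent simulator at small population size
    until the instance fits ``max_vertices`` (total), carries at least one
    mutation, and -- with ``require_non_t_coalescent`` -- contains at least
    one coalescent vertex that is not t-coalescent.  Deterministic in
    ``seed``.
    """
    if not 2 <= K <= 4:
        raise ArgError(f"K={K} outside the brute-force range 2..4")
    if not 1 <= M <= 3:
        raise ArgError(f"M={M} outside the brute-force range 1..3")
    if require_non_t_coalescent and M < 2:
        raise ArgError("a single-tree ARG has no non-t-coalescent coalescence")
    cfg = SimConfig(
        K=K,
        N=N,
        M=M,
        junction_recomb_probs=recomb if M > 1 else 0.0,
        mutation_rate=mutation_rate,
    )
    for attempt in range(1000):
        rng = np.random.default_rng([seed, attempt])
        arg = simulate_binary_arg(cfg, rng)
        if len(arg.vertices) > max_vertices:
            continue
        if require_non_t_coalescent and not any(
            not arg.is_leaf(v)
            and len(arg.children(v)) >= 2
            and not is_t_coalescent(arg, v)
            for v in arg.vertices
        ):
            continue
        arg = annotate_mutations(arg, cfg, rng)
        if not any(s.labels for s in arg.strands):
            continue
        return arg
    raise RuntimeError(
        f"no admissible instance in 1000 attempts (K={K}, M={M}, "
        f"max_vertices={max_vertices}, seed={seed})"
    )
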
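"""Small example networks with closed-form or enumerable optima.

These fixtures (all <= 8 reactions, all with finite bounds so the flux
polytope is bounded) are used throughout the test-suite to cross-check
the LP solver against exhaustive vertex enumeration, and are handy for
demonstrating the machinery at the REPL.
"""

from __future__ import annotations

from .core import CouplingConstraint, MetabolicModel, Reaction

__all__ = ["linear_chain", "branched_cofactor", "coupled_pair", "reference_suite"]


def _m(mid: str, reactions: list[Reaction], couplings=(), objective=None) -> MetabolicModel:
    model = MetabolicModel(id=mid)
    for r in reactions:
        model.add_reaction(r)
    model.couplings = list(couplings)
    model.objective_id = objective
    model.validate()
    return model


def linear_chain(uptake: float = 5.0) -> MetabolicModel:
    """A[e] -> A[c] -> B[c] -> B[e]; max EX_B equals the uptake bound."""
    return _m(
        "chain",
        [
            Reaction("EX_A[e]", {"A[e]": -1}, -uptake, 0),
            Reaction("At", {"A[e]": -1, "A[c]": 1}, 0, 100),
            Reaction("AB", {"A[c]": -1, "B[c]": 1}, 0, 100),
            Reaction("Bt", {"B[c]": -1, "B[e]": 1}, 0, 100),
            Reaction("EX_B[e]", {"B[e]": -1}, 0, 100),
        ],
        objective="EX_B[e]",
    )


def branched_cofactor() -> MetabolicModel:
    """Branched toy with a 2:1 cofactor split.

    A is taken up (<= 6) and split between a direct route A->P and a
    cofactor-demanding route A + 2 cof -> P, with cof regenerated from A.
    """
    return _m(
        "branched",
        [
            Reaction("EX_A[e]", {"A[e]": -1}, -6, 0),
            Reaction("At", {"A[e]": -1, "A[c]": 1}, 0, 50),
            Reaction("direct", {"A[c]": -1, "P[c]": 1}, 0, 2),
            Reaction("cofmake", {"A[c]": -1, "cof[c]": 1}, 0, 50),
            Reaction("cofuse", {"A[c]": -1, "cof[c]": -2, "P[c]": 1}, 0, 50),
            Reaction("EX_P[c]", {"P[c]": -1}, 0, 50),
        ],
        objective="EX_P[c]",
    )


def coupled_pair(factor: float = 400.0) -> MetabolicModel:
    """Secretion coupled to a biomass reaction: flux dies when biomass does."""
    return _m(
        "coupled",
        [
            Reaction("EX_S[e]", {"S[e]": -1}, -10, 0),
            Reaction("St", {"S[e]": -1, "S[c]": 1}, 0, 100),
            Reaction("biomass", {"S[c]": -1}, 0, 0.01),
            Reaction("ferm", {"S[c]": -1, "F[c]": 1}, 0, 100),
            Reaction("EX_F[c]", {"F[c]": -1}, 0, 100),
        ],
        couplings=[
            CouplingConstraint("ferm", "biomass", factor),
            CouplingConstraint("EX_F[c]", "biomass", factor),
        ],
        objective="EX_F[c]",
    )


def reference_suite() -> list[MetabolicModel]:
    """>= 10 bounded fixtures, each with an objective, for oracle checks."""
    fixtures = [
        linear_chain(5.0),
        linear_chain(2.5),
        branched_cofactor(),
        coupled_pair(400.0),
        coupled_pair(2.0),
        # reversible shuttle: net export limited by uptake
        _m(
            "shuttle",
            [
                Reaction("EX_X[e]", {"X[e]": -1}, -4, 4),
                Reaction("Xt", {"X[e]": -1, "X[c]": 1}, -20, 20),
                Reaction("XY", {"X[c]": -1, "Y[c]": 1}, -20, 20),
                Reaction("EX_Y[c]", {"Y[c]": -1}, -3, 20),
            ],
            objective="EX_Y[c]",
        ),
        # stoichiometric 2:1 conversion
        _m(
            "doubler",
            [
                Reaction("EX_A[e]", {"A[e]": -1}, -7, 0),
                Reaction("split", {"A[e]": -1, "B[c]": 2}, 0, 100),
                Reaction("EX_B[c]", {"B[c]": -1}, 0, 100),
            ],
            objective="EX_B[c]",
        ),
        # competing sinks with one limiting substrate
        _m(
            "competition",
            [
                Reaction("EX_A[e]", {"A[e]": -1}, -10, 0),
                Reaction("toP", {"A[e]": -1, "P[c]": 1}, 0, 6),
                Reaction("toQ", {"A[e]": -1, "Q[c]": 1}, 0, 6),
                Reaction("EX_P[c]", {"P[c]": -1}, 0, 100),
                Reaction("EX_Q[c]", {"Q[c]": -1}, 0, 100),
            ],
            objective="EX_P[c]",
        ),
        # fixed-flux reaction forces its own range
        _m(
            "fixed",
            [
                Reaction("EX_A[e]", {"A[e]": -1}, -10, 0),
                Reaction("pump", {"A[e]": -1, "B[c]": 1}, 2, 2),
                Reaction("EX_B[c]", {"B[c]": -1}, 0, 100),
            ],
            objective="EX_B[c]",
        ),
        # internal loop plus export; loop bounded by reaction bounds
        _m(
            "loop",
            [
                Reaction("EX_A[e]", {"A[e]": -1}, -3, 0),
                Reaction("AB", {"A[e]": -1, "B[c]": 1}, 0, 9),
                Reaction("BC", {"B[c]": -1, "C[c]": 1}, -9, 9),
                Reaction("CB", {"C[c]": -1, "B[c]": 1}, -9, 9),
                Reaction("EX_C[c]", {"C[c]": -1}, 0, 9),
            ],
            objective="EX_C[c]",
        ),
        # two substrates feeding one product through an AND-stoichiometry
        _m(
            "and_gate",
            [
                Reaction("EX_A[e]", {"A[e]": -1}, -8, 0),
                Reaction("EX_B[e]", {"B[e]": -1}, -3, 0),
                Reaction("join", {"A[e]": -1, "B[e]": -1, "P[c]": 1}, 0, 100),
                Reaction("EX_P[c]", {"P[c]": -1}, 0, 100),
            ],
            objective="EX_P[c]",
        ),
        # blocked branch: no path from substrate to the objective product
        _m(
            "blocked",
            [
                Reaction("EX_A[e]", {"A[e]": -1}, -5, 0),
                Reaction("AB", {"A[e]": -1, "B[c]": 1}, 0, 10),
                Reaction("EX_B[c]", {"B[c]": -1}, 0, 10),
                Reaction("EX_Z[c]", {"Z[c]": -1}, 0, 10),
                Reaction("Zt", {"Z[c]": -1, "W[c]": 1}, 0, 10),
                Reaction("DM_W[c]", {"W[c]": -1}, 0, 0),
            ],
            objective="EX_Z[c]",
        ),
    ]
    return fixtures
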
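import pytest

from mclx.network import MetabolicNetwork, Reaction, parse_equation


def make_net(rows, name="test-net"):
    """Compact network builder: rows of (id, equation, lb, ub[, gpr[, subsystem]])."""
    net = MetabolicNetwork(name=name)
    for row in rows:
        rid, equation, lb, ub = row[:4]
        gpr = row[4] if len(row) > 4 else ""
        subsystem = row[5] if len(row) > 5 else ""
        stoich = parse_equation(equation)
        net.add_reaction(
            Reaction(rid, stoich, float(lb), float(ub), gpr=gpr,
                     subsystem=subsystem),
            declare_metabolites=True,
        )
    return net


@pytest.fixture
def chain_net():
    """EX_in(0..10) supplies A, R1(0..5) converts A->B, EX_out(0..1000) drains B.

    The flux through all three reactions is equal at steady state and the
    R1 capacity of 5 is the bottleneck.
    """
    return make_net(
        [
            ("EX_in", "-> 1 A[e]", 0, 10),
            ("R1", "1 A[e] -> 1 B[e]", 0, 5),
            ("EX_out", "1 B[e] ->", 0, 1000),
        ]
    )


@pytest.fixture
def loop_net():
    """Two reversible reactions forming an internal (type III) cycle."""
    return make_net(
        [
            ("R1", "1 A[c] <=> 1 B[c]", -1000, 1000),
            ("R2", "1 B[c] <=> 1 A[c]", -1000, 1000),
        ]
    )
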
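import numpy as np
import pytest

from orgnet import ConfirmedNetwork, Organization, Roster, get_layer


def make_roster(n: int, n_nonrespondents: int = 0, org_type: str = "NGO") -> Roster:
    orgs = [
        Organization(
            org_id=f"ORG{k:02d}",
            acronym=f"O{k}",
            full_name=f"Organization {k}",
            org_type=org_type,
            n_countries=(k % 8) + 1,
            respondent=(k >= n_nonrespondents),
        )
        for k in range(n)
    ]
    return Roster.from_organizations(orgs)


def net_from_adj(adj: np.ndarray, layer: str | None = "overall") -> ConfirmedNetwork:
    nodes = tuple(f"ORG{k:02d}" for k in range(len(adj)))
    return ConfirmedNetwork(nodes, adj, get_layer(layer) if layer else None)


@pytest.fixture
def roster5() -> Roster:
    return make_roster(5)


@pytest.fixture
def star5() -> ConfirmedNetwork:
    adj = np.zeros((5, 5), dtype=int)
    adj[0, 1:] = adj[1:, 0] = 1
    return net_from_adj(adj)


def path_graph(n: int) -> ConfirmedNetwork:
    adj = np.zeros((n, n), dtype=int)
    for k in range(n - 1):
        adj[k, k + 1] = adj[k + 1, k] = 1
    return net_from_adj(adj)


def cycle_graph(n: int) -> ConfirmedNetwork:
    adj = np.zeros((n, n), dtype=int)
    for k in range(n):
        adj[k, (k + 1) % n] = adj[(k + 1) % n, k] = 1
    return net_from_adj(adj)


def complete_graph(n: int) -> ConfirmedNetwork:
    adj = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
    return net_from_adj(adj)


def empty_graph(n: int) -> ConfirmedNetwork:
    return net_from_adj(np.zeros((n, n), dtype=int))
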
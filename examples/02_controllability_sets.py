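"""Hubs, minimum dominating set and connected dominating set of a network.

Uses the built-in 20-node toy network.  Domination is directed: a node
covers itself and the nodes it regulates.  The MDS is solved to proven
optimality by an integer linear program; the MCDS (a dominating set of the
largest connected component that also induces a connected subgraph) comes
from a grow-and-prune heuristic.
"""

from topcontrol import compute_mcds, compute_mds, degrees, hubs, largest_connected_component
from topcontrol.synthetic import generate_toy_network

net = generate_toy_network()
print(f"toy network: {len(net)} nodes, {net.n_edges()} edges")

top = sorted(degrees(net), key=lambda r: -r.degree)[:3]
print("highest degrees:", ", ".join(f"{r.node}={r.degree}" for r in top))

hub_set = hubs(net, fraction=0.10)
print(f"hubs (top 10% = {len(hub_set)} nodes): {sorted(hub_set.members)}")

mds = compute_mds(net, mode="exact")
print(f"MDS ({mds.exactness}, size {len(mds)}): {sorted(mds.members)}")

lcc = largest_connected_component(net)
mcds = compute_mcds(net)
print(f"LCC has {len(lcc)} nodes; MCDS ({mcds.exactness}, size {len(mcds)}): {sorted(mcds.members)}")

# Every node is regulated by (or is) an MDS member; the MCDS additionally
# forms one connected 'dominating pathway' through the LCC, hence is larger.
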
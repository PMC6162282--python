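"""Maximum flow through a small signaling motif, with its min-cut certificate.

Builds the classic diamond network (two 2-hop routes from source to sink
plus a cross edge), runs Edmonds-Karp, and prints the augmenting paths, the
flow value, and the minimum cut — whose capacity equals the flow value by
the max-flow min-cut theorem. The exhaustive cut-enumeration oracle
confirms the value independently.
"""

from rppaflow import generate_flow_fixture, max_flow, min_cut_by_enumeration

fixture = generate_flow_fixture("diamond")
result = max_flow(fixture.flownet, "s", "t")

print("arc capacities:", dict(sorted(fixture.flownet.capacities.items())))
for path, bottleneck in result.augmenting_paths:
    print(f"augmenting path {' -> '.join(path)}  pushes {bottleneck}")
print(f"maximum flow:   {result.value}")
print(f"minimum cut:    {sorted(result.min_cut_arcs)}  "
      f"(capacity {sum(fixture.flownet.capacities[a] for a in result.min_cut_arcs)})")
print(f"enumeration oracle agrees: {min_cut_by_enumeration(fixture.flownet, 's', 't')}")

# The flow of 5 saturates both arcs leaving the source, so {s->a, s->b} is
# the bottleneck separating s from t.
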
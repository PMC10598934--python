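"""Export the inferred causal diagram between the four risk scores as DOT.

Collects every direction labelled causal (causation or combination) from the
reported coefficient table into a weighted digraph and prints Graphviz DOT;
edge labels carry the causal effect and Pr, line thickness the effect size.
Familial-confounding links are recorded in the JSON metadata, not drawn.

Run:  python examples/causal_diagram.py > diagram.dot  (then `dot -Tpdf ...`)
"""

import json
import sys

from icefalcon.pipeline import export_graph
from icefalcon.reference import DISPLAY_NAMES, reported_pair_results

graph = export_graph(reported_pair_results(include_adjusted=False), DISPLAY_NAMES)
print(graph.to_dot())

print(f"\n// {len(graph.edges)} causal edges; omitted (non-causal) directions:", file=sys.stderr)
for o in graph.metadata["omitted_directions"]:
    print(f"//   {o['source']} -> {o['target']}: {o['label']}", file=sys.stderr)
print("// JSON form:", file=sys.stderr)
print(json.dumps(graph.to_json_dict(), indent=2), file=sys.stderr)
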
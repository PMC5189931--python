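"""Load the packaged EMT network and report its structural composition.

The counts are the bookkeeping identity of the model: 97 nodes split
into 74 molecular species and 23 gene loci, 169 interactions, and 251
searched parameters (169 kinetic + 38 control + 44 saturation).
"""

import json

from emtensemble import count_components, load_packaged_model, validate_model

model = load_packaged_model()
violations = validate_model(model)
print(f"validation violations: {len(violations)}")

counts = count_components(model)
print(json.dumps(counts.as_dict(), indent=2))
# nodes = molecular_species + genes; total_params = kinetic + control + saturation
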
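"""Experiment configuration: the XML schema that wires two sites together.

Builds the default two-site configuration, serialises it to the EDL-style
XML, reparses it (round trip) and shows the transmitting channel element —
the same structure that controls what is exchanged, when, and where.
"""

import duoscan as ds

config = ds.default_config(n_sites=2, seed=1)
xml = ds.serialize_edl(config)

assert ds.parse_edl(xml) == config  # lossless round trip

print(xml[: xml.index("<RECEIVEMODULE")])
print("...")
ch = config.output_channels[0]
print(f"site {ch.site_id} transmits {list(ch.output_params)} at block-local "
      f"scan(s) {list(ch.trigger_scans)} to '{ch.location}' "
      f"({ch.mode}, timestamped={ch.write_timestamp})")
print(f"schedule: {config.schedule_params.runs_per_task} runs per task, "
      f"{config.schedule_params.scans_per_block}-scan blocks, tasks "
      f"{list(config.schedule_params.tasks)}")
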
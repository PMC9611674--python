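# Reference banana-chain scenario: warm loading, 14-day cooled transport,
# 12 h harbor gap, 4-day ripening. Queries 1.5 and 3 days after departure.
shipment_ids: ["4711"]
packing_start: 0.0
transport_start: 6.0
harbor_start: 342.0
ripening_start: 354.0
end: 450.0
t_load: 26.0
setpoint: 13.2
true_k_m: 0.05
ripening_q: 0.3
supply_noise: 0.05
box_noise: 0.05
sampling_interval: 1.0
ambient: 18.0
harbor_k: 0.02
seed: 42
queries:
  - {at: 42.0}
  - {at: 78.0, setpoint_delta: -0.5}
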
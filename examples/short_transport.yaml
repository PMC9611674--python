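shipment_ids: ["7001"]
packing_start: 0.0
transport_start: 2.0
harbor_start: 74.0
ripening_start: 80.0
end: 104.0
supply_noise: 0.0
box_noise: 0.0
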
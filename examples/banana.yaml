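Bananas:
  CoolIdent:
    Topic_In: Transports_Shipment_#ID_Sensors
    Topic_Out: Transports_Shipment_#ID_CoolPara
    LifeCycleTranslate:
      Start_Transport: Start_Model
      Arrive_Transport: Stop_Model
  CoolPredict:
    Topic_In: Transports_Shipment_#ID_CoolPara
    Topic_Out: Transports_Shipment_#ID_CoolPred
    LifeCycleTranslate:
      Start_Transport: Start_Model
      Stop_Ripening: Stop_Model
  RipeHeat:
    Topic_In: Transports_Shipment_#ID_CoolPred
    Topic_Out: Transports_Shipment_#ID_RipePara
    LifeCycleTranslate:
      Start_Transport: Start_Collect
      Arrive_Transport: Stop_Collect
      Start_Ripening: Start_Model
      Stop_Ripening: Stop_Model
  GreenLife:
    Topic_In: Transports_Shipment_#ID_RipePara
    Topic_Out: Transports_Shipment_#ID_GreenLife
    LifeCycleTranslate:
      Start_Transport: Start_Model
      Stop_Ripening: Stop_Model
models:
  CoolIdent: {stable_after: 72.0, spread_window: 24.0, spread_tol: 0.02}
  CoolPredict: {supply_window: 24, chilling_floor: 12.5}
  RipeHeat: {smoothing_window: 5}
  GreenLife: {GL0: 28.0, Q10: 3.0, T_ref: 13.0}
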
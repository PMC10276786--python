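outcome_id,direction,arm,events,total
response_rate,favorable,treatment,143,177
response_rate,favorable,comparator,226,342
discontinuation_ae,unfavorable,treatment,7,206
discontinuation_ae,unfavorable,comparator,10,432
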
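medium,pH,experimental_mg_mL,predicted_siva_mg_mL
FeSSIF+CH+OA,6.9,3.71,2.03
FeSSIF+CH+OA,6.2,4.1,2.03
FeSSIF+CH+OA,5,0.52,2.03
FeSSIF,6.99,1.24,2.03
FeSSIF,6.2,0.94,2.03
FeSSIF,4.8,1.94,2.03
FaSSIF,6.5,0.36,0.71
FaSSIF+CH+OA,6.5,0.17,0.71
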
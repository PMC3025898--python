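product_name,insulin_class,insulin_type
HUMULIN N,basal,human
NOVOLIN N,basal,human
RELION/NOVOLIN N,basal,human
INSULATARD,basal,human
HUMULIN L,basal,human
NOVOLIN L,basal,human
HUMULIN U,basal,human
LEVEMIR,basal,analog
LANTUS,basal,analog
HUMULIN 50/50,mixture,human
HUMULIN 70/30,mixture,human
NOVOLIN 70/30,mixture,human
RELION NOVOLIN 70/30,mixture,human
HUMALOG MIX 50/50,mixture,analog
HUMALOG MIX 75/25,mixture,analog
NOVOLOG MIX 70/30,mixture,analog
NOVOLOG,mealtime,analog
APIDRA,mealtime,analog
HUMALOG,mealtime,analog
LISPRO-PFC,mealtime,analog
HUMULIN R,mealtime,human
NOVOLIN R,mealtime,human
RELION/NOVOLIN R,mealtime,human
HUMULIN BR,mealtime,human
VELOSULIN BR,mealtime,human
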
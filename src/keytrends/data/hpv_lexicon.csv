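keyword,category
public expense,positive
subsidy,positive
signature campaign,positive
recruitment,positive
vaccine,neutral
screening,neutral
cervarix,neutral
prevention,neutral
vaccination,neutral
side effect,negative
infertility,negative
danger,negative
[an attorney's name],negative
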
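# systemic anti-infectives (starter list, ATC J01 antibacterials /
# J02 antifungals / J05 antivirals by common name); one name per line
amoxicillin
amoxicillin/clavulanate
ampicillin
azithromycin
cefazolin
cefepime
ceftriaxone
cefuroxime
ciprofloxacin
clarithromycin
clindamycin
doxycycline
ertapenem
gentamicin
levofloxacin
linezolid
meropenem
metronidazole
moxifloxacin
nitrofurantoin
penicillin v
piperacillin/tazobactam
sulfamethoxazole/trimethoprim
tobramycin
vancomycin
fluconazole
itraconazole
posaconazole
voriconazole
amphotericin b
caspofungin
micafungin
aciclovir
acyclovir
valaciclovir
valacyclovir
ganciclovir
valganciclovir
oseltamivir
zanamivir
remdesivir
ribavirin
foscarnet
cidofovir
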
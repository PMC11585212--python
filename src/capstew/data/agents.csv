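code,agent_class,display_name,synonyms
benzylpenicillin,natural_penicillin,Benzylpenicillin,penicillin g|benzyl penicillin|pcg|j01ce01
phenoxymethylpenicillin,natural_penicillin,Phenoxymethylpenicillin,penicillin v|phenoxymethyl penicillin|pcv|j01ce02
ampicillin,aminopenicillin,Ampicillin,j01ca01
amoxicillin,aminopenicillin,Amoxicillin,amoxycillin|j01ca04
pivmecillinam,aminopenicillin,Pivmecillinam,mecillinam|j01ca08
erythromycin,macrolide,Erythromycin,j01fa01
azithromycin,macrolide,Azithromycin,j01fa10
clarithromycin,macrolide,Clarithromycin,j01fa09
roxithromycin,macrolide,Roxithromycin,j01fa06
spiramycin,macrolide,Spiramycin,j01fa02
gentamicin,aminoglycoside,Gentamicin,gentamycin|j01gb03
tobramycin,aminoglycoside,Tobramycin,j01gb01
amikacin,aminoglycoside,Amikacin,j01gb06
cefotaxime,cephalosporin_3g,Cefotaxime,j01dd01
ceftriaxone,cephalosporin_3g,Ceftriaxone,j01dd04
ceftazidime,cephalosporin_3g,Ceftazidime,j01dd02
piperacillin_tazobactam,penicillin_bli,Piperacillin/tazobactam,piperacillin/tazobactam|piperacillin-tazobactam|pip-tazo|tazocin|j01cr05
amoxicillin_clavulanate,penicillin_bli,Amoxicillin/clavulanate,amoxicillin/clavulanate|amoxicillin-clavulanate|co-amoxiclav|augmentin|j01cr02
ciprofloxacin,quinolone,Ciprofloxacin,ciprofloksacin|j01ma02
levofloxacin,quinolone,Levofloxacin,j01ma12
moxifloxacin,quinolone,Moxifloxacin,j01ma14
ofloxacin,quinolone,Ofloxacin,j01ma01
clindamycin,lincosamide,Clindamycin,j01ff01
doxycycline,tetracycline,Doxycycline,j01aa02
tetracycline,tetracycline,Tetracycline,j01aa07
lymecycline,tetracycline,Lymecycline,j01aa04
cefuroxime,other,Cefuroxime,j01da06
cefalexin,other,Cefalexin,cephalexin|j01db01
meropenem,other,Meropenem,j01dh02
vancomycin,other,Vancomycin,j01xa01
trimethoprim_sulfamethoxazole,other,Trimethoprim/sulfamethoxazole,trimethoprim/sulfamethoxazole|cotrimoxazole|co-trimoxazole|bactrim|j01ee01
metronidazole,other,Metronidazole,j01xd01
nitrofurantoin,other,Nitrofurantoin,j01xe01
linezolid,other,Linezolid,j01xx08
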
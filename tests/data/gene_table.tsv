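gene	chr	start	end
ABHD2	15	89631380	89745591
RLBP1	15	89753097	89764922
FANCI	15	89787193	89860362
POLG	15	89859535	89878026
MIR6766	15	89869969	89870041
COLEC12	18	319354	500729
CETN1	18	580368	581524
CLUL1	18	596997	650293
C18orf56	18	649619	658340
TYMS	18	657603	673499
ENOSF1	18	670323	712662
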
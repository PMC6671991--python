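field,raw,canonical
agency,no effect,no effect
agency,ne,no effect
agency,nlaa,NLAA
agency,may affect not likely to adversely affect,NLAA
agency,"may affect, not likely to adversely affect",NLAA
agency,not likely to adversely affect,NLAA
agency,laa,LAA
agency,likely to adversely affect,LAA
agency,may affect likely to adversely affect,LAA
agency,proposed no jeopardy,proposed no jeopardy
agency,no jeopardy,proposed no jeopardy
agency,proposed jeopardy,proposed jeopardy
agency,jeopardy,proposed jeopardy
expert,no effect,no effect
expert,ne,no effect
expert,nlaa,NLAA
expert,may affect not likely to adversely affect,NLAA
expert,"may affect, not likely to adversely affect",NLAA
expert,not likely to adversely affect,NLAA
expert,no jeopardy,no jeopardy
expert,no jeopardy or adverse modification,no jeopardy
expert,jeopardy,jeopardy
expert,jeopardy and/or adverse modification,jeopardy
critical_habitat,no effect,no effect
critical_habitat,nlaa,NLAA
critical_habitat,not likely to adversely affect,NLAA
critical_habitat,no adverse modification,no adverse modification
critical_habitat,no adverse mod,no adverse modification
critical_habitat,adverse modification,adverse modification
critical_habitat,adverse mod,adverse modification
critical_habitat,no critical habitat,no critical habitat
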